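# Methods

## Scope and model

`epseq` implements the computational half of a sort-seq deep mutational
scanning (DMS) workflow on a yeast-displayed enzyme. The measurement
model is:

1. Every plasmid carries one enzyme variant and one or more 15-nt
   barcodes (UMIs). Long-read sequencing of the plasmid pool yields
   "pre-LUT" records (barcode, barcode quality, variant call, indel
   count); the package's input boundary is this digested record, not the
   raw long reads.
2. Cells displaying the library are FACS-sorted into 4 bins along a
   fluorescence axis (display level for the expression screen; a
   proximity-labeling activity stain for the activity screen). Bin 1 is
   placed to capture 99% of a non-fluorescent negative control; the
   remaining three gates split the expressing population into equal
   thirds.
3. Each bin is sequenced to ~25 reads per sorted cell; reads reduce to
   their UMI, are tagged (size → quality → table lookup), and tag-1
   reads are counted per variant.
4. Fitness is estimated by the weighted-mean chain
   `c_v = r_v·c_tot/r_tot`, `β = Σωc/Σc`, `F = log2(β_v/β_wt)`, with a
   cell-weighted consensus across replicates.

The estimator assumes (a) reads sample sorted cells proportionally
within a bin, (b) the bin median ω is an adequate summary of the
fluorescence of all cells in the bin, and (c) the wild-type clone scored
in the same experiment is a valid reference. Because each cell's
fluorescence is collapsed to its bin's median, the 4-bin readout
compresses extreme fitness values toward the gate range (visible in the
worked example: a true log2 fitness of −0.7 reads out around −0.5). The
estimator is monotone in the true value, so rank structure and
correlations are preserved; users needing absolute effect sizes should
treat |F| as a lower bound at the distribution tails.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `read_depth_factor` | 25 | reads/sorted cell | matches the sequencing-to-sorting ratio the workflow is designed around |
| `sigma_log2_fi` | 0.5 | log2 fluorescence units | per-cell spread of the display signal; the real instrument's value is not published, so this is a documented free parameter of the generator |
| `mu_wt_fi` / `mu_neg_fi` | 10 000 / 100 | arbitrary fluorescence units | two-decade separation between displaying cells and autofluorescence, typical of antibody-stained yeast |
| `gates.neg_quantile` | 0.99 | — | gate 1 captures 99% of the negative control |
| `gates.n_expressing_bins` | 3 | — | expressing cells split into equal thirds |
| min mean barcode quality | Q20 | Phred | applied as ≥ 20 uniformly (the source pipeline mixes "higher than" and "≥" phrasing); configurable |
| `min_cells` support filter | 10 | cells | variants below 10 total reads-derived cells are dropped from final reporting |
| neutral-range multiplier k | 1 | SD | neutrality = within mean ± k·SD of synonymous scores; k is configurable because only the ± convention, not a cutoff rule, is established |
| interface `contact_cutoff` | 5.0 | Å | heavy-atom inter-chain contact distance defining the dimer interface |
| SASA `n_points` | 960 | — | golden-spiral quadrature points per atom; exact for isolated atoms, ~1% for overlaps; raise to ~4000 when sub-percent rotational stability matters |

## Synthetic data generator

The generator emulates: NNK site-saturation structure (≤19 missense + 1
nonsense (TAG) + synonymous-where-realizable per codon), multi-barcode
variants, barcode conflicts in the pre-LUT at a configurable rate,
log-normal per-cell fluorescence with geometric mean scaled by
`2**f_true` (so the log2-ratio estimator targets `f_true` exactly),
gate placement per the 99%-negative / equal-thirds scheme, multinomial
cell sorting, Poisson read totals at 25×, multinomial read sampling over
cells, and per-base UMI sequencing errors.

Deliberate simplifications: no FACS optical artifacts (doublets,
spillover), no PacBio consensus errors beyond the injected conflicts, no
staggered-primer offset structure in the short reads (the UMI sits
between two fixed flanks and is recovered by anchored matching with a
1-mismatch budget), equal cell allocation per variant by default
(optional Dirichlet skew), and a wild-type clone overrepresented 10×
(`wt_cell_multiplier`) so the shared β_wt reference is stable — in a
real library WT abundance varies, and a noisier β_wt shifts every score
coherently. Passing recovery tests therefore demonstrates estimator
correctness under the stated noise model, not robustness to instrument-
specific artifacts.

Default truth values: missense fitness uniform on (−0.8, 0.3) (the
span such screens typically report), nonsense fitness −0.7 except for
positions in the last ~4% of the chain (truncation there leaves a
functional enzyme, so truth is 0), synonymous fitness exactly 0.
Activity truth equals expression truth unless per-position
`activity_hotspots` deltas are planted.

## Numerical and design choices

- **Fractional cells.** `c_v = r_v·c_tot/r_tot` is not rounded;
  rounding biases low-count variants. A bin with `r_tot = 0` contributes
  0 cells with a warning.
- **No pseudo-counts.** A variant observed only in bin 1 still gets
  β = ω₁ > 0; unobserved variants are excluded, not imputed.
- **r_tot** in the reads→cells conversion is the bin's own column sum of
  counted (tag-1, in-target) reads, so unassignable reads do not dilute
  the conversion.
- **LUT tie-breaking** compares, per conflicting call: supporting-read
  count, then the maximum mean barcode quality among its reads, then the
  minimum indel count; all ties ⇒ the barcode is discarded. The cascade
  is evaluated on sorted call identities, making the table independent
  of record order. Out-of-window calls stay in the table flagged
  `in_target_region=False` and are excluded at counting time.
- **Tag precedence** is size (tag 3) → quality (tag 2, which also
  absorbs UMIs containing N) → lookup (1/0); the tag definitions do not
  themselves impose an order, so one is fixed and documented here.
- **Consensus weights** `c_vj` are reads-derived cells summed over bins
  within a replicate (not FACS event counts).
- **Empty bins** get a placeholder ω at the geometric midpoint of their
  gate so downstream metadata stays positive; they contribute no cells.
- **Gate ties**: a cell exactly on a threshold sorts into the lower bin,
  consistent with gate 1 capturing cells *at or below* its threshold.
- **Expression floor** for normalized activity is recomputed from the
  dataset at hand as nonsense mean + 1 SD rather than hard-coded.
- **Interface detection** uses inter-chain heavy-atom contacts within
  5 Å — a deliberate substitution for buried-surface-area tools, chosen
  for determinism and zero external dependencies; the cutoff is exposed.
- **Shrake–Rupley SASA** is implemented in-package with a deterministic
  golden-spiral point set (equal-area, so isolated atoms are exact) and
  a KD-tree neighbor search; hydrogens are ignored; HETATM groups
  occlude but are not reported; altloc resolves to highest occupancy
  (ties: first encountered). Relative SASA divides by a Tien-style
  theoretical maximum per residue type and caps at 100. The radii,
  max-ASA and property-scale tables (Kyte–Doolittle hydrophobicity,
  Zimmerman bulkiness and polarity) are module-level dictionaries meant
  to be overridden; Δscale is mutant − wild type (negate for the
  opposite convention).
- **Active site**: the catalytic center has no canonical atom-set
  definition, so it must be supplied explicitly — either a coordinate
  triple or the name of a HETATM group whose centroid is used.
- **Position averages** use missense variants only; stop substitutions
  keep their own row in the heatmap export. Hotspot ranking breaks
  normalized-activity ties by variant id, and position-frequency ties by
  position number, so results are permutation-invariant.
- **Correlations** use pairwise-complete deletion and report two-sided
  p values with no multiple-testing correction (panel n's differ for the
  same reason). Per-variant vs per-position correlation modes are both
  available since published panels mix the two.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data
sized for a laptop: the neutrality check uses 300 synonymous variants ×
100 cells at 25× depth (~0.8 M reads, seconds), and the recovery check
uses 500 variants × 100 cells × 2 replicates (~2.5 M reads). Recovery
quality at these sizes: Pearson r(estimate, truth) ≈ 0.97,
between-replicate r ≈ 0.95; synonymous mean |F| < 0.03.

## Known limitations

- Only the weighted-mean estimator is implemented — no
  maximum-likelihood or regression-based sort-seq estimators.
- The 4-bin compression biases extreme fitness magnitudes toward zero
  (monotone, rank-preserving).
- ΔΔG prediction, conservation scoring, read mapping and long-read
  consensus are upstream tools; their outputs are consumed as TSV inputs
  only.
- The structural module expects a reasonably clean PDB file; insertion
  codes are carried through keys but features are reported per residue
  number, and a user-supplied mapping is needed when library codon
  numbering differs from structure numbering.
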