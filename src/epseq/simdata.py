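"""Synthetic sort-seq experiment generator with known ground truth.

Emulates a site-saturation (NNK) deep-mutational-scanning experiment on a
yeast-displayed enzyme read out by 4-way FACS sorting and UMI sequencing:

1. an NNK library over a window of codons, each variant carrying one or
   more 15-nt UMIs, exported as digested long-read ("pre-LUT") records
   with optional barcode conflicts injected;
2. per-cell fluorescence, log-normal around the wild-type geometric mean
   scaled by the variant's true fitness (``2**f_true``), so the ratio of
   geometric means equals the fitness ratio the estimator targets;
3. gate placement — gate 1 captures 99% of a non-fluorescent negative
   control, the remaining gates split expressing cells into equal-sized
   sub-populations;
4. multinomial sorting and read sampling at ~25 reads per sorted cell,
   with per-base UMI sequencing errors.

Every stage is driven by a single ``numpy`` Generator so fixed seeds
reproduce byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._genetics import AA_TO_NNK_CODONS, AMINO_ACIDS, NNK_STOP_CODONS, STOP
from .counts import BinMeta
from .lut import OUT_OF_RANGE_CALL, PreLutRecord

WT_ID = "WT"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class GateSpec:
    """FACS gating scheme: one negative gate plus equal expressing bins."""

    neg_quantile: float = 0.99
    n_expressing_bins: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.neg_quantile < 1:
            raise ValueError("neg_quantile must be in (0, 1)")
        if self.n_expressing_bins < 1:
            raise ValueError("n_expressing_bins must be >= 1")

    @property
    def n_bins(self) -> int:
        return self.n_expressing_bins + 1


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic sort-seq experiment.

    Defaults follow the study conditions the pipeline is designed for: a
    4-bin sort, ~25 reads per sorted cell, per-cell log2-fluorescence SD
    of 0.5, missense fitness spanning roughly (-0.8, 0.3) in log2 units,
    nonsense fitness -0.7 except near the C terminus, and a negative
    control two orders of magnitude dimmer than wild type.
    """

    wt_protein: str
    n_positions: int
    start_position: int = 2
    barcodes_per_variant: float = 3.0
    n_cells_total: int = 50_000
    read_depth_factor: float = 25.0
    sigma_log2_fi: float = 0.5
    mu_wt_fi: float = 10_000.0
    mu_neg_fi: float = 100.0
    umi_error_rate: float = 0.001
    conflict_rate: float = 0.0
    seed: int = 0
    gates: GateSpec = field(default_factory=GateSpec)
    wt_cell_multiplier: float = 10.0
    nonsense_fitness: float = -0.7
    nonsense_neutral_after: int | None = None
    f_exp_range: tuple[float, float] = (-0.8, 0.3)
    activity_hotspots: dict[int, float] = field(default_factory=dict)
    dirichlet_alpha: float | None = None

    def __post_init__(self) -> None:
        if len(self.wt_protein) < 2:
            raise ValueError("degenerate protein: length must be >= 2")
        if self.n_positions < 1:
            raise ValueError("n_positions must be >= 1")
        last = self.start_position + self.n_positions - 1
        if self.start_position < 1 or last > len(self.wt_protein):
            raise ValueError("mutagenized window exceeds protein length")
        for name in ("umi_error_rate", "conflict_rate"):
            rate = getattr(self, name)
            if not 0 <= rate <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.mu_wt_fi <= 0 or self.mu_neg_fi <= 0:
            raise ValueError("fluorescence means must be > 0")
        if self.read_depth_factor <= 0:
            raise ValueError("read_depth_factor must be > 0")
        if self.sigma_log2_fi < 0:
            raise ValueError("sigma_log2_fi must be >= 0")

    @property
    def positions(self) -> range:
        return range(self.start_position, self.start_position + self.n_positions)

    def cterm_neutral_after(self) -> int:
        """Position after which nonsense variants are treated as neutral.

        Stop codons very close to the C terminus leave an essentially
        full-length, functional protein; by default the last ~4% of the
        chain (the 350-of-365 proportion) is considered past the point
        where truncation hurts.
        """
        if self.nonsense_neutral_after is not None:
            return self.nonsense_neutral_after
        return int(round(len(self.wt_protein) * 350 / 365))


@dataclass
class SimTruth:
    """Ground truth for one library variant."""

    variant_id: str
    position: int
    wt_aa: str
    mut_aa: str
    variant_class: str  # synonymous | missense | nonsense | wt
    f_true_exp: float
    f_true_act: float
    umis: list[str]
    wt_codon: str = ""
    mut_codon: str = ""


@dataclass
class SimLibrary:
    truths: list[SimTruth]
    prelut_records: list[PreLutRecord]
    conflicted_umis: set[str]

    def umi_map(self) -> dict[str, str]:
        """The intended UMI -> variant assignment (pre-conflict truth)."""
        return {u: t.variant_id for t in self.truths for u in t.umis}

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": [t.variant_id for t in self.truths],
                "position": [t.position for t in self.truths],
                "wt_aa": [t.wt_aa for t in self.truths],
                "mut_aa": [t.mut_aa for t in self.truths],
                "variant_class": [t.variant_class for t in self.truths],
                "wt_codon": [t.wt_codon for t in self.truths],
                "mut_codon": [t.mut_codon for t in self.truths],
                "f_true_exp": [t.f_true_exp for t in self.truths],
                "f_true_act": [t.f_true_act for t in self.truths],
                "n_umis": [len(t.umis) for t in self.truths],
            }
        )


def _random_umis(n: int, rng: np.random.Generator, taken: set[str]) -> list[str]:
    out: list[str] = []
    while len(out) < n:
        codes = rng.integers(0, 4, size=(n - len(out), 15), dtype=np.uint8)
        flat = _BASES[codes].tobytes().decode()
        for i in range(0, len(flat), 15):
            umi = flat[i: i + 15]
            if umi not in taken:
                taken.add(umi)
                out.append(umi)
    return out


def generate_library(config: SimConfig) -> SimLibrary:
    """Build the NNK variant library, its UMIs and the pre-LUT records.

    Per mutagenized codon the library holds up to 19 missense variants,
    at most one nonsense variant (TAG is the only NNK stop), and a
    synonymous variant where the wild-type residue has more than one NNK
    codon.  A ``conflict_rate`` fraction of UMIs is additionally linked
    to a second, random variant in the pre-LUT output to exercise the
    conflict-resolution rules downstream.
    """
    rng = np.random.default_rng(config.seed)
    truths: list[SimTruth] = [
        SimTruth(WT_ID, 0, "", "", "wt", 0.0, 0.0, [])
    ]
    cterm = config.cterm_neutral_after()

    for pos in config.positions:
        wt_aa = config.wt_protein[pos - 1]
        nnk = AA_TO_NNK_CODONS.get(wt_aa)
        if not nnk:
            raise ValueError(f"residue {wt_aa!r} at {pos} has no NNK codon")
        wt_codon = nnk[0]
        for mut_aa in AMINO_ACIDS:
            if mut_aa == wt_aa:
                continue
            f = float(rng.uniform(*config.f_exp_range))
            f_act = f + config.activity_hotspots.get(pos, 0.0)
            truths.append(
                SimTruth(
                    f"{wt_aa}{pos}{mut_aa}", pos, wt_aa, mut_aa, "missense",
                    f, f_act, [], wt_codon, AA_TO_NNK_CODONS[mut_aa][0],
                )
            )
        if len(nnk) > 1:
            truths.append(
                SimTruth(
                    f"{wt_aa}{pos}{wt_aa}", pos, wt_aa, wt_aa, "synonymous",
                    0.0, 0.0, [], wt_codon, nnk[1],
                )
            )
        f_stop = 0.0 if pos > cterm else config.nonsense_fitness
        truths.append(
            SimTruth(
                f"{wt_aa}{pos}{STOP}", pos, wt_aa, STOP, "nonsense",
                f_stop, f_stop, [], wt_codon, NNK_STOP_CODONS[0],
            )
        )

    taken: set[str] = set()
    for truth in truths:
        n_umis = max(1, int(rng.poisson(config.barcodes_per_variant)))
        truth.umis = _random_umis(n_umis, rng, taken)

    records: list[PreLutRecord] = []
    conflicted: set[str] = set()
    variant_ids = [t.variant_id for t in truths]
    read_no = 0

    def emit(umi: str, variant_id: str, n_reads: int) -> None:
        nonlocal read_no
        for _ in range(n_reads):
            records.append(
                PreLutRecord(
                    read_id=f"ccs/{read_no}",
                    umi=umi,
                    umi_mean_q=float(np.round(rng.uniform(20, 40), 2)),
                    variant_call=variant_id,
                    n_indels=int(rng.poisson(0.1)),
                )
            )
            read_no += 1

    for truth in truths:
        for umi in truth.umis:
            n_reads = 1 + int(rng.poisson(2))
            emit(umi, truth.variant_id, n_reads)
            if config.conflict_rate > 0 and rng.random() < config.conflict_rate:
                conflicted.add(umi)
                other = variant_ids[int(rng.integers(len(variant_ids)))]
                if other == truth.variant_id:
                    other = OUT_OF_RANGE_CALL
                emit(umi, other, int(rng.integers(1, n_reads + 1)))

    return SimLibrary(truths, records, conflicted)


def simulate_cell_fluorescence(
    f_true: float, n_cells: int, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-cell fluorescence: log-normal around ``mu_wt_fi * 2**f_true``.

    Per-cell log2 intensity is Normal(log2(mu_wt_fi) + f_true,
    sigma_log2_fi), so the population geometric mean scales as 2**f_true
    relative to wild type — the quantity the log2-ratio fitness score
    recovers.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    log2_fi = rng.normal(
        math.log2(config.mu_wt_fi) + f_true, config.sigma_log2_fi, size=n_cells
    )
    return np.exp2(log2_fi)


def simulate_negative_control(
    n_cells: int, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Autofluorescence-only population used to place gate 1."""
    log2_fi = rng.normal(
        math.log2(config.mu_neg_fi), config.sigma_log2_fi, size=n_cells
    )
    return np.exp2(log2_fi)


def place_gates(
    negative_control_fi: np.ndarray,
    expressing_fi: np.ndarray,
    spec: GateSpec = GateSpec(),
) -> np.ndarray:
    """Compute bin thresholds from negative-control and expressing cells.

    Threshold 1 sits at the ``neg_quantile`` quantile of the negative
    control, capturing that fraction of non-fluorescent cells in gate 1;
    the remaining thresholds split the expressing cells above it into
    ``n_expressing_bins`` equal-occupancy bins.
    """
    neg = np.asarray(negative_control_fi, dtype=float)
    expr = np.asarray(expressing_fi, dtype=float)
    if neg.size == 0 or expr.size == 0:
        raise ValueError("both populations must be non-empty")
    t1 = float(np.quantile(neg, spec.neg_quantile))
    above = expr[expr > t1]
    if above.size == 0:
        raise ValueError("no expressing population above the negative gate")
    inner = np.quantile(
        above, [i / spec.n_expressing_bins for i in range(1, spec.n_expressing_bins)]
    )
    thresholds = np.concatenate([[t1], inner])
    if not np.all(np.diff(thresholds) > 0):
        raise ValueError("gate thresholds are not strictly increasing")
    return thresholds


def assign_bins(fi: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """1-based bin index per cell; a cell exactly on a threshold goes low."""
    return np.searchsorted(thresholds, fi, side="left") + 1


@dataclass
class ReadSet:
    """UMI reads emitted for one bin (qualities are per-read mean Phred)."""

    umis: list[str]
    mean_q: np.ndarray

    def __len__(self) -> int:
        return len(self.umis)


@dataclass
class SortSeqReplicate:
    """One replicate of the sorted, sequenced experiment."""

    read_sets: dict[int, ReadSet]
    metas: list[BinMeta]
    sorted_cells: pd.DataFrame  # index variant_id, columns bin ids
    thresholds: np.ndarray


def _emit_reads(
    truths: Sequence[SimTruth],
    reads_per_variant: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> ReadSet:
    rows: list[np.ndarray] = []
    counts: list[int] = []
    for truth, n_reads in zip(truths, reads_per_variant):
        if n_reads == 0:
            continue
        per_umi = rng.multinomial(n_reads, [1 / len(truth.umis)] * len(truth.umis))
        for umi, k in zip(truth.umis, per_umi):
            if k:
                rows.append(np.frombuffer(umi.encode(), dtype=np.uint8))
                counts.append(int(k))
    if not rows:
        return ReadSet([], np.zeros(0))
    arr = np.repeat(np.stack(rows), counts, axis=0)
    if config.umi_error_rate > 0:
        mask = rng.random(arr.shape) < config.umi_error_rate
        if mask.any():
            # substitute with a uniformly random *different* base
            base_idx = np.searchsorted(_BASES, arr[mask])
            shift = rng.integers(1, 4, size=mask.sum())
            arr[mask] = _BASES[(base_idx + shift) % 4]
    flat = arr.tobytes().decode()
    umis = [flat[i: i + 15] for i in range(0, len(flat), 15)]
    return ReadSet(umis, np.full(len(umis), 37.0))


def simulate_sort_and_sequence(
    truths: Sequence[SimTruth],
    config: SimConfig,
    rng: np.random.Generator,
    thresholds: np.ndarray | None = None,
    assay: str = "expression",
) -> SortSeqReplicate:
    """Sort one replicate of the library and sequence each bin.

    Cells are allocated to variants (equal by default, wild type gets
    ``wt_cell_multiplier`` times more, optional Dirichlet skew), given
    log-normal fluorescence scaled by true fitness, gated, and each bin
    is sequenced to an expected depth of ``read_depth_factor`` reads per
    sorted cell with multinomial read sampling over cells and per-base
    UMI errors.
    """
    if assay not in ("expression", "activity"):
        raise ValueError("assay must be 'expression' or 'activity'")
    truths = list(truths)
    n_var = len(truths)
    weights = np.ones(n_var)
    for i, t in enumerate(truths):
        if t.variant_class == "wt":
            weights[i] = config.wt_cell_multiplier
    if config.dirichlet_alpha is not None:
        weights = weights * rng.dirichlet(np.full(n_var, config.dirichlet_alpha))
    weights = weights / weights.sum()
    cells_v = np.maximum(1, np.floor(config.n_cells_total * weights)).astype(int)

    f_true = np.array(
        [t.f_true_exp if assay == "expression" else t.f_true_act for t in truths]
    )
    cell_variant = np.repeat(np.arange(n_var), cells_v)
    log2_fi = rng.normal(
        math.log2(config.mu_wt_fi) + f_true[cell_variant], config.sigma_log2_fi
    )
    fi = np.exp2(log2_fi)

    if thresholds is None:
        neg = simulate_negative_control(
            min(config.n_cells_total, 100_000), config, rng
        )
        thresholds = place_gates(neg, fi, config.gates)

    bins = assign_bins(fi, thresholds)
    n_bins = config.gates.n_bins
    variant_ids = [t.variant_id for t in truths]
    sorted_cells = pd.DataFrame(
        0, index=pd.Index(variant_ids, name="variant_id"),
        columns=range(1, n_bins + 1), dtype=int,
    )
    read_sets: dict[int, ReadSet] = {}
    metas: list[BinMeta] = []

    for b in range(1, n_bins + 1):
        in_bin = bins == b
        c_tot = int(in_bin.sum())
        tally = np.bincount(cell_variant[in_bin], minlength=n_var)
        sorted_cells[b] = tally
        if c_tot > 0:
            omega = float(np.median(fi[in_bin]))
        else:  # empty bin: geometric midpoint of its gate
            lo = thresholds[b - 2] if b >= 2 else thresholds[0] / 4
            hi = thresholds[b - 1] if b <= len(thresholds) else thresholds[-1] * 4
            omega = float(np.sqrt(lo * hi))
        if c_tot == 0:
            read_sets[b] = ReadSet([], np.zeros(0))
            metas.append(BinMeta(b, omega, 0, 0))
            continue
        r_tot = int(rng.poisson(config.read_depth_factor * c_tot))
        reads_per_variant = rng.multinomial(r_tot, tally / c_tot)
        read_sets[b] = _emit_reads(truths, reads_per_variant, config, rng)
        metas.append(BinMeta(b, omega, c_tot, r_tot))

    return SortSeqReplicate(read_sets, metas, sorted_cells, np.asarray(thresholds))


# ---------------------------------------------------------------------------
# File export


def write_fastq(read_set: ReadSet, path: str | Path, flanks=None) -> None:
    """Write a bin's reads as Phred-33 FASTQ with the UMI between flanks."""
    from .counts import FlankSpec

    flanks = flanks or FlankSpec()
    with open(path, "w") as fh:
        for i, (umi, q) in enumerate(zip(read_set.umis, read_set.mean_q)):
            seq = flanks.flank5 + umi + flanks.flank3
            qual = chr(33 + int(round(q))) * len(seq)
            fh.write(f"@read/{i}\n{seq}\n+\n{qual}\n")


def write_truth(library: SimLibrary, path: str | Path) -> None:
    library.truth_frame().to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t",
        dtype={"variant_id": str, "wt_aa": str, "mut_aa": str,
               "wt_codon": str, "mut_codon": str},
        keep_default_na=False,
    )
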