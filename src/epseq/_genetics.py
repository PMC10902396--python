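"""Standard genetic code and NNK degenerate-codon helpers.

The codon table is written out explicitly (rather than delegating to a
sequence library) because variant classification — synonymous vs missense
vs nonsense — is a core rule of the pipeline and is cross-checked against
an independent translation oracle in the test suite.
"""

from __future__ import annotations

STOP = "*"

CODON_TABLE: dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": STOP, "TAG": STOP,
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": STOP, "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

AMINO_ACIDS = sorted(set(CODON_TABLE.values()) - {STOP})

#: NNK codons: any base at positions 1-2, G or T at position 3.  The set
#: encodes all 20 amino acids plus a single stop (TAG), which is why NNK
#: site-saturation libraries yield at most 19 missense + 1 nonsense + the
#: synonymous substitutions realizable for the wild-type residue.
NNK_CODONS = sorted(c for c in CODON_TABLE if c[2] in "GT")

NNK_STOP_CODONS = [c for c in NNK_CODONS if CODON_TABLE[c] == STOP]

AA_TO_NNK_CODONS: dict[str, list[str]] = {}
for _codon in NNK_CODONS:
    AA_TO_NNK_CODONS.setdefault(CODON_TABLE[_codon], []).append(_codon)


def translate_codon(codon: str) -> str:
    """Translate one codon; raises ValueError on anything not in the code."""
    codon = codon.upper()
    if codon not in CODON_TABLE:
        raise ValueError(f"invalid codon: {codon!r}")
    return CODON_TABLE[codon]
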