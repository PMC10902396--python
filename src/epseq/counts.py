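"""Per-bin UMI extraction, tagging and variant read counting.

Short reads from each FACS bin carry a 15-nt UMI between two constant
flanking sequences.  Each read is reduced to its UMI and the UMI's mean
Phred quality, then tagged:

* tag 3 — UMI length differs from 15 nt (size check comes first);
* tag 2 — mean quality below Q20, or the UMI contains an ``N``;
* tag 1 — passes both checks and is present in the look-up table;
* tag 0 — passes both checks but is absent from the table.

Only tag-1 reads whose LUT call lies inside the mutagenized region are
counted, yielding the variants x bins read-count table consumed by the
fitness estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .lut import UMI_LENGTH, LookupTable

logger = logging.getLogger(__name__)

TAG_IN_LUT = 1
TAG_NOT_IN_LUT = 0
TAG_LOW_QUALITY = 2
TAG_BAD_SIZE = 3

DEFAULT_MIN_Q = 20.0


@dataclass(frozen=True)
class FlankSpec:
    """Constant sequences bordering the UMI within a read."""

    flank5: str = "TCTAGAGC"
    flank3: str = "GCGGCCGC"
    umi_length: int = UMI_LENGTH
    max_mismatches: int = 1

    def read_length(self) -> int:
        return len(self.flank5) + self.umi_length + len(self.flank3)


@dataclass(frozen=True)
class BinMeta:
    """Sorting metadata for one FACS bin.

    omega is the median fluorescence of the cells sorted into the bin —
    the weighting factor of the fitness estimator; c_tot the number of
    cells sorted; r_tot the total number of assigned reads.
    """

    bin_id: int
    omega: float
    c_tot: float
    r_tot: float = 0.0

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError("omega must be > 0")
        if self.c_tot < 0 or self.r_tot < 0:
            raise ValueError("c_tot and r_tot must be >= 0")


class TaggedUmi(NamedTuple):
    umi: str
    tag: int


def _hamming_le(a: str, b: str, budget: int) -> bool:
    mismatches = 0
    for x, y in zip(a, b):
        if x != y:
            mismatches += 1
            if mismatches > budget:
                return False
    return True


def extract_umi(
    seq: str, qualities: Sequence[float] | np.ndarray, flanks: FlankSpec
) -> tuple[str, float] | None:
    """Locate the UMI between the two constant flanks of a read.

    Returns ``(umi, mean_phred)`` or None when no flank placement within
    the mismatch budget exists.  An exact-match fast path handles the
    overwhelming majority of reads; otherwise every offset is scanned
    with a Hamming budget of ``max_mismatches`` per flank.
    """
    f5, f3, k = flanks.flank5, flanks.flank3, flanks.umi_length
    span = len(f5) + k

    def _at(i: int) -> tuple[str, float] | None:
        umi = seq[i + len(f5): i + span]
        q = qualities[i + len(f5): i + span]
        return umi, float(np.mean(q))

    i = seq.find(f5)
    while i != -1:
        if seq[i + span: i + span + len(f3)] == f3 and i + span + len(f3) <= len(seq):
            return _at(i)
        i = seq.find(f5, i + 1)

    if flanks.max_mismatches > 0:
        m = flanks.max_mismatches
        for i in range(len(seq) - span - len(f3) + 1):
            if _hamming_le(seq[i: i + len(f5)], f5, m) and _hamming_le(
                seq[i + span: i + span + len(f3)], f3, m
            ):
                return _at(i)
    return None


def tag_umi(
    umi: str, mean_q: float, lut: LookupTable, min_q: float = DEFAULT_MIN_Q
) -> TaggedUmi:
    """Tag one UMI with precedence size -> quality -> LUT lookup."""
    if len(umi) != UMI_LENGTH:
        return TaggedUmi(umi, TAG_BAD_SIZE)
    if mean_q < min_q or "N" in umi:
        return TaggedUmi(umi, TAG_LOW_QUALITY)
    return TaggedUmi(umi, TAG_IN_LUT if umi in lut else TAG_NOT_IN_LUT)


def count_bin(
    tagged: Iterable[TaggedUmi], lut: LookupTable
) -> tuple[pd.Series, dict[int, int]]:
    """Count tag-1 reads per variant for one bin.

    Returns ``(r_v, tag_counts)`` where ``r_v`` is indexed by variant
    call (reads of all UMIs belonging to the same variant are summed) and
    ``tag_counts`` is the full tag partition of the input reads.  Reads
    whose LUT entry lies outside the target region are excluded from
    ``r_v`` (they still count toward tag 1 in the partition).
    """
    tag_counts = {0: 0, 1: 0, 2: 0, 3: 0}
    variant_reads: dict[str, int] = {}
    for umi, tag in tagged:
        tag_counts[tag] += 1
        if tag != TAG_IN_LUT:
            continue
        entry = lut[umi]
        if not entry.in_target_region:
            continue
        variant_reads[entry.variant_call] = variant_reads.get(entry.variant_call, 0) + 1
    r_v = pd.Series(variant_reads, dtype="int64").sort_index()
    r_v.index.name = "variant_id"
    if r_v.sum() == 0:
        logger.warning("bin contains zero usable (tag-1, in-target) reads")
    return r_v, tag_counts


def tag_reads(
    umis: Sequence[str],
    mean_qs: Sequence[float] | np.ndarray,
    lut: LookupTable,
    min_q: float = DEFAULT_MIN_Q,
) -> list[TaggedUmi]:
    return [tag_umi(u, q, lut, min_q) for u, q in zip(umis, mean_qs)]


def count_reads_vectorized(
    umis: Sequence[str],
    mean_qs: Sequence[float] | np.ndarray,
    lut: LookupTable,
    min_q: float = DEFAULT_MIN_Q,
) -> tuple[pd.Series, dict[int, int]]:
    """Vectorized equivalent of ``tag_reads`` + ``count_bin``.

    Used for large simulated bins; agrees read-for-read with the scalar
    path (asserted in the test suite).
    """
    if len(umis) == 0:
        empty = pd.Series(dtype="int64")
        empty.index.name = "variant_id"
        return empty, {0: 0, 1: 0, 2: 0, 3: 0}
    s = pd.Series(umis, dtype="object")
    q = np.asarray(mean_qs, dtype=float)
    bad_size = s.str.len() != UMI_LENGTH
    low_q = (~bad_size) & ((q < min_q) | s.str.contains("N", regex=False))
    call = s.map({u: e.variant_call for u, e in lut.entries.items()})
    in_target = s.map({u: e.in_target_region for u, e in lut.entries.items()})
    in_lut = (~bad_size) & (~low_q) & call.notna()
    not_in_lut = (~bad_size) & (~low_q) & call.isna()
    tag_counts = {
        0: int(not_in_lut.sum()),
        1: int(in_lut.sum()),
        2: int(low_q.sum()),
        3: int(bad_size.sum()),
    }
    usable = call[in_lut & in_target.eq(True)]
    r_v = usable.value_counts().sort_index().astype("int64")
    r_v.index.name = "variant_id"
    if r_v.sum() == 0:
        logger.warning("bin contains zero usable (tag-1, in-target) reads")
    return r_v, tag_counts


def count_fastq(
    path: str | Path,
    lut: LookupTable,
    flanks: FlankSpec,
    min_q: float = DEFAULT_MIN_Q,
) -> tuple[pd.Series, dict[int, int], int]:
    """Extract, tag and count UMIs from one bin's FASTQ file.

    Returns ``(r_v, tag_counts, n_unextracted)``; reads in which no flank
    placement is found are reported separately and take no tag.
    """
    from Bio import SeqIO

    tagged: list[TaggedUmi] = []
    n_miss = 0
    for rec in SeqIO.parse(str(path), "fastq"):
        hit = extract_umi(str(rec.seq), rec.letter_annotations["phred_quality"], flanks)
        if hit is None:
            n_miss += 1
            continue
        tagged.append(tag_umi(hit[0], hit[1], lut, min_q))
    r_v, tag_counts = count_bin(tagged, lut)
    return r_v, tag_counts, n_miss


@dataclass
class BinCountTable:
    """Variants x bins read counts plus per-bin sorting metadata."""

    reads: pd.DataFrame  # index variant_id, one int column per bin_id
    metas: dict[int, BinMeta]

    def __post_init__(self) -> None:
        missing = set(self.reads.columns) - set(self.metas)
        if missing:
            raise ValueError(f"bins without metadata: {sorted(missing)}")

    @property
    def bin_ids(self) -> list[int]:
        return sorted(self.reads.columns)

    def r_tot(self, bin_id: int) -> float:
        return float(self.reads[bin_id].sum())


def build_count_table(
    per_bin_counts: dict[int, pd.Series], metas: Sequence[BinMeta]
) -> BinCountTable:
    reads = pd.DataFrame(per_bin_counts).fillna(0).astype("int64").sort_index()
    reads.index.name = "variant_id"
    reads = reads[sorted(reads.columns)]
    return BinCountTable(reads=reads, metas={m.bin_id: m for m in metas})


def write_counts(table: BinCountTable, path: str | Path) -> None:
    long = (
        table.reads.stack()
        .rename("r_v")
        .rename_axis(["variant_id", "bin"])
        .reset_index()
    )
    long.to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path, metas: Sequence[BinMeta]) -> BinCountTable:
    long = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    reads = long.pivot(index="variant_id", columns="bin", values="r_v")
    reads = reads.fillna(0).astype("int64")
    reads.columns = reads.columns.astype(int)
    return BinCountTable(reads=reads, metas={m.bin_id: m for m in metas})


_META_COLUMNS = ["bin_id", "omega", "c_tot", "r_tot"]


def write_bin_meta(metas: Sequence[BinMeta], path: str | Path) -> None:
    pd.DataFrame(
        [[m.bin_id, m.omega, m.c_tot, m.r_tot] for m in metas],
        columns=_META_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_bin_meta(path: str | Path) -> list[BinMeta]:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != _META_COLUMNS:
        raise ValueError(f"{path}: unexpected bin metadata columns {list(df.columns)}")
    return [
        BinMeta(int(r.bin_id), float(r.omega), float(r.c_tot), float(r.r_tot))
        for r in df.itertuples()
    ]
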