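"""UMI -> variant look-up table (LUT) construction.

The LUT links each 15-nt plasmid barcode (UMI) observed in long-read
sequencing of the barcoded library to the enzyme variant carried by that
plasmid.  Because a barcode can be observed on several reads — and,
rarely, attached to contradictory variant calls (template switching,
sequencing error, barcode collision) — building the table requires a
deterministic conflict-resolution policy:

1. keep the call supported by strictly more independent reads;
2. otherwise the call with strictly higher maximum mean barcode quality;
3. otherwise the call whose reads carry strictly fewer indels;
4. if all three criteria tie, the barcode is discarded entirely.

Barcodes whose length differs from 15 nt, or that contain ``N`` bases,
never enter the table.  Calls that fall outside the mutagenized region
are kept but flagged ``in_target_region=False`` so downstream counting
can exclude them.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

UMI_LENGTH = 15
DEFAULT_MIN_MEAN_Q = 20.0

#: Sentinel variant calls.
WT_CALL = "WT"
OUT_OF_RANGE_CALL = "OUT_OF_RANGE"


@dataclass(frozen=True)
class PreLutRecord:
    """One digested long read: barcode, its quality, and the variant call."""

    read_id: str
    umi: str
    umi_mean_q: float
    variant_call: str
    n_indels: int

    def __post_init__(self) -> None:
        if self.umi_mean_q < 0:
            raise ValueError("umi_mean_q must be >= 0")
        if self.n_indels < 0:
            raise ValueError("n_indels must be >= 0")
        if set(self.umi) - set("ACGTN"):
            raise ValueError(f"UMI contains non-ACGTN characters: {self.umi!r}")


@dataclass(frozen=True)
class LutEntry:
    variant_call: str
    support_reads: int
    mean_q: float
    in_target_region: bool = True


@dataclass
class LookupTable:
    """Mapping of unique 15-nt UMIs to resolved variant calls."""

    entries: dict[str, LutEntry] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, umi: str) -> bool:
        return umi in self.entries

    def __getitem__(self, umi: str) -> LutEntry:
        return self.entries[umi]

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def variant_of(self, umi: str) -> str | None:
        entry = self.entries.get(umi)
        return entry.variant_call if entry is not None else None

    def validate(self) -> None:
        for umi in self.entries:
            if len(umi) != UMI_LENGTH:
                raise ValueError(f"UMI {umi!r} is not {UMI_LENGTH} nt")
            if "N" in umi:
                raise ValueError(f"UMI {umi!r} contains N")


def filter_records(
    records: Iterable[PreLutRecord], min_mean_q: float = DEFAULT_MIN_MEAN_Q
) -> list[PreLutRecord]:
    """Keep records whose mean barcode Phred quality is >= ``min_mean_q``.

    The >= convention is applied uniformly; the threshold is exposed so a
    strict-inequality pipeline can be emulated with ``min_mean_q=20.0001``.
    Input order is preserved.
    """
    if min_mean_q < 0:
        raise ValueError("min_mean_q must be >= 0")
    return [r for r in records if r.umi_mean_q >= min_mean_q]


def _resolve_one(records: list[PreLutRecord]) -> LutEntry | None:
    """Apply the support/quality/indel cascade to one UMI's records."""
    by_call: dict[str, list[PreLutRecord]] = {}
    for rec in records:
        by_call.setdefault(rec.variant_call, []).append(rec)

    def stats(call: str) -> tuple[int, float, int]:
        recs = by_call[call]
        return (
            len(recs),
            max(r.umi_mean_q for r in recs),
            min(r.n_indels for r in recs),
        )

    candidates = sorted(by_call)  # sorted for order-independence
    for key, best in (
        (lambda c: stats(c)[0], max),  # more supporting reads
        (lambda c: stats(c)[1], max),  # higher max mean quality
        (lambda c: stats(c)[2], min),  # fewer indels
    ):
        extreme = best(key(c) for c in candidates)
        candidates = [c for c in candidates if key(c) == extreme]
        if len(candidates) == 1:
            break
    if len(candidates) != 1:
        return None  # unresolvable conflict: drop the UMI

    call = candidates[0]
    n_reads, max_q, _ = stats(call)
    return LutEntry(
        variant_call=call,
        support_reads=n_reads,
        mean_q=max_q,
        in_target_region=call != OUT_OF_RANGE_CALL,
    )


def resolve_conflicts(records: Iterable[PreLutRecord]) -> LookupTable:
    """Collapse pre-LUT records into a unique UMI -> variant table.

    UMIs of length != 15 or containing N are removed.  The result is
    independent of input record order.
    """
    groups: dict[str, list[PreLutRecord]] = {}
    for rec in records:
        if len(rec.umi) != UMI_LENGTH or "N" in rec.umi:
            continue
        groups.setdefault(rec.umi, []).append(rec)

    table = LookupTable()
    for umi in sorted(groups):
        entry = _resolve_one(groups[umi])
        if entry is not None:
            table.entries[umi] = entry
    return table


def build_lut(
    records: Iterable[PreLutRecord], min_mean_q: float = DEFAULT_MIN_MEAN_Q
) -> LookupTable:
    """Quality-filter pre-LUT records and resolve them into a LUT."""
    return resolve_conflicts(filter_records(records, min_mean_q))


_LUT_COLUMNS = ["umi", "variant_call", "support_reads", "mean_q", "in_target_region"]


def write_lut(table: LookupTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_LUT_COLUMNS)
        for umi in sorted(table.entries):
            e = table.entries[umi]
            writer.writerow(
                [umi, e.variant_call, e.support_reads, repr(e.mean_q),
                 int(e.in_target_region)]
            )


def read_lut(path: str | Path) -> LookupTable:
    table = LookupTable()
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != _LUT_COLUMNS:
            raise ValueError(f"{path}: line 1: unexpected LUT header {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(_LUT_COLUMNS):
                raise ValueError(f"{path}: line {lineno}: expected "
                                 f"{len(_LUT_COLUMNS)} fields, got {len(row)}")
            umi, call, support, mean_q, in_target = row
            try:
                entry = LutEntry(call, int(support), float(mean_q),
                                 bool(int(in_target)))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            if len(umi) != UMI_LENGTH or set(umi) - set("ACGT"):
                raise ValueError(f"{path}: line {lineno}: invalid UMI {umi!r}")
            if umi in table.entries:
                raise ValueError(f"{path}: line {lineno}: duplicate UMI {umi!r}")
            table.entries[umi] = entry
    return table


_PRELUT_COLUMNS = ["read_id", "umi", "umi_mean_q", "variant_call", "n_indels"]


def write_prelut(records: Iterable[PreLutRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_PRELUT_COLUMNS)
        for r in records:
            writer.writerow(
                [r.read_id, r.umi, repr(r.umi_mean_q), r.variant_call, r.n_indels]
            )


def read_prelut(path: str | Path) -> list[PreLutRecord]:
    records = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != _PRELUT_COLUMNS:
            raise ValueError(f"{path}: line 1: unexpected pre-LUT header {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(_PRELUT_COLUMNS):
                raise ValueError(f"{path}: line {lineno}: expected "
                                 f"{len(_PRELUT_COLUMNS)} fields, got {len(row)}")
            try:
                records.append(
                    PreLutRecord(row[0], row[1], float(row[2]), row[3], int(row[4]))
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return records
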