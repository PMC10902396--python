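"""Shared fixtures: tiny simulated experiments and synthetic PDB builders.

All structural fixtures are synthetic, generated in memory at test time;
no experimental structure file ships with the package.
"""

from __future__ import annotations

import numpy as np
import pytest

from epseq import lut as lut_mod
from epseq.lut import LookupTable, LutEntry
from epseq.simdata import SimConfig, SimTruth, WT_ID


def pdb_atom_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resseq: int,
    xyz: tuple[float, float, float],
    occupancy: float = 1.0,
    bfactor: float = 0.0,
    element: str = "C",
    altloc: str = " ",
    record: str = "ATOM",
) -> str:
    x, y, z = xyz
    name_field = f" {name:<3}" if len(name) < 4 else name
    return (
        f"{record:<6}{serial:>5} {name_field}{altloc}{resname:>3} {chain}"
        f"{resseq:>4}    {x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}{bfactor:6.2f}"
        f"          {element:>2}\n"
    )


@pytest.fixture
def write_pdb(tmp_path):
    def _write(lines: list[str], name: str = "model.pdb"):
        path = tmp_path / name
        path.write_text("".join(lines) + "END\n")
        return path

    return _write


def make_flat_truths(
    n_variants: int,
    rng: np.random.Generator,
    f_true=None,
    variant_class: str = "missense",
    umis_per_variant: int = 2,
) -> list[SimTruth]:
    """WT plus n variants with explicit fitness, each with unique UMIs."""
    taken: set[str] = set()

    def umis(k: int) -> list[str]:
        out = []
        while len(out) < k:
            u = "".join("ACGT"[i] for i in rng.integers(0, 4, 15))
            if u not in taken:
                taken.add(u)
                out.append(u)
        return out

    truths = [SimTruth(WT_ID, 0, "", "", "wt", 0.0, 0.0, umis(umis_per_variant))]
    for i in range(n_variants):
        f = 0.0 if f_true is None else float(np.atleast_1d(f_true)[i])
        mut = "A" if variant_class == "synonymous" else "V"
        truths.append(
            SimTruth(
                f"A{i + 2}{mut}", i + 2, "A", mut, variant_class,
                f, f, umis(umis_per_variant),
            )
        )
    return truths


def lut_from_truths(truths) -> LookupTable:
    """Exact LUT for a truth set, bypassing pre-LUT resolution."""
    table = LookupTable()
    for t in truths:
        for u in t.umis:
            table.entries[u] = LutEntry(t.variant_id, 1, 35.0, True)
    return table


@pytest.fixture
def small_config() -> SimConfig:
    return SimConfig(
        wt_protein="MALVRSGTKW", n_positions=3, n_cells_total=3000,
        barcodes_per_variant=2.0, seed=11,
    )
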