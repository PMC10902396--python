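"""Per-residue structural features from a PDB file.

For a homodimeric flavoenzyme structure (with its FAD cofactor and any
bound ligand as HETATM groups) this module computes, per residue:

* relative solvent-accessible surface area (Shrake–Rupley, 0–100 after
  normalization by a residue-type maximum);
* Cα B-factor;
* mean Cα distance to the cofactor's atoms;
* Cα distance to the nearest dimer-interface residue (0 on the
  interface, which is detected by inter-chain heavy-atom contacts);
* Cα distance to the active site (an explicit point or the centroid of a
  ligand residue);
* hydrophobicity / bulkiness / polarity scales of the wild-type residue.

All reference tables (van der Waals radii, maximum ASA, property scales)
are module-level dictionaries meant to be overridden by callers who
prefer different conventions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

PROBE_RADIUS = 1.4  # water probe, Angstrom

#: Van der Waals radii by element (Angstrom); unknown elements fall back
#: to carbon with a warning.
VDW_RADII: dict[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "H": 1.20, "SE": 1.90, "FE": 1.80, "ZN": 1.39, "MG": 1.73,
}
DEFAULT_RADIUS = 1.70

#: Theoretical maximum ASA per residue type (Tien-style values, A^2),
#: used to express per-residue SASA on the 0-100 relative scale.
MAX_ASA: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLU": "E", "GLN": "Q", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# Editable residue property scales (Kyte-Doolittle hydrophobicity,
# Zimmerman bulkiness, Zimmerman polarity).  Shipped as configuration:
# any 20-residue table with the same keys may be substituted.
HYDROPHOBICITY: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "E": -3.5, "Q": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}
BULKINESS: dict[str, float] = {
    "A": 11.50, "R": 14.28, "N": 12.82, "D": 11.68, "C": 13.46,
    "E": 13.57, "Q": 14.45, "G": 3.40, "H": 13.69, "I": 21.40,
    "L": 21.40, "K": 15.71, "M": 16.25, "F": 19.80, "P": 17.43,
    "S": 9.47, "T": 15.77, "W": 21.67, "Y": 18.03, "V": 21.57,
}
POLARITY: dict[str, float] = {
    "A": 0.00, "R": 52.00, "N": 3.38, "D": 49.70, "C": 1.48,
    "E": 49.90, "Q": 3.53, "G": 0.00, "H": 51.60, "I": 0.13,
    "L": 0.13, "K": 49.50, "M": 1.43, "F": 0.35, "P": 1.58,
    "S": 1.67, "T": 1.66, "W": 2.10, "Y": 1.61, "V": 0.13,
}

DEFAULT_SCALES = {
    "hydrophobicity": HYDROPHOBICITY,
    "bulkiness": BULKINESS,
    "polarity": POLARITY,
}


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray
    occupancy: float
    bfactor: float


@dataclass
class Residue:
    chain: str
    resseq: int
    icode: str
    resname: str
    atoms: dict[str, Atom] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.resseq, self.icode)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.resname, "X")

    def ca(self) -> Atom | None:
        return self.atoms.get("CA")

    def heavy_coords(self) -> np.ndarray:
        pts = [a.coord for a in self.atoms.values() if a.element != "H"]
        return np.array(pts) if pts else np.empty((0, 3))


@dataclass
class StructureModel:
    """Protein chains plus HETATM groups keyed by residue name."""

    residues: list[Residue]
    het_groups: dict[str, list[Atom]] = field(default_factory=dict)

    @property
    def chains(self) -> list[str]:
        return sorted({r.chain for r in self.residues})

    def chain_residues(self, chain: str) -> list[Residue]:
        return [r for r in self.residues if r.chain == chain]


def parse_pdb(path: str | Path, include_waters: bool = False) -> StructureModel:
    """Parse a PDB file into a flat structure model.

    Uses Bio.PDB underneath; disordered atoms resolve to the
    highest-occupancy altloc.  HETATM residues (cofactors, ligands) are
    collected per residue name; waters are dropped unless requested.
    """
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("model", str(path))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise ValueError(f"{path}: no ATOM records") from None

    residues: list[Residue] = []
    het_groups: dict[str, list[Atom]] = {}
    for chain in model:
        for res in chain:
            hetfield, resseq, icode = res.id
            atoms = [
                Atom(
                    name=a.get_name(),
                    element=(a.element or "").strip().upper(),
                    coord=np.array(a.get_coord(), dtype=float),
                    occupancy=float(a.get_occupancy() or 1.0),
                    bfactor=float(a.get_bfactor() or 0.0),
                )
                for a in res.get_atoms()  # DisorderedAtom -> top occupancy
            ]
            if hetfield.strip():  # HETATM
                if res.get_resname().strip() == "HOH" and not include_waters:
                    continue
                het_groups.setdefault(res.get_resname().strip(), []).extend(atoms)
            else:
                residues.append(
                    Residue(chain.id, resseq, icode.strip(),
                            res.get_resname().strip(),
                            {a.name: a for a in atoms})
                )
    if not residues:
        raise ValueError(f"{path}: no protein ATOM records")
    return StructureModel(residues, het_groups)


# ---------------------------------------------------------------------------
# Shrake-Rupley SASA


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def _atom_radius(element: str, radii: dict[str, float]) -> float:
    r = radii.get(element.upper())
    if r is None:
        warnings.warn(f"unknown element {element!r}: using default radius")
        return DEFAULT_RADIUS
    return r


def sasa_atoms(
    coords: np.ndarray,
    radii_values: np.ndarray,
    probe: float = PROBE_RADIUS,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Shrake-Rupley).

    Each atom's solvent sphere (vdW + probe radius) is sampled with a
    deterministic golden-spiral point set; the accessible fraction is the
    share of points outside every neighbouring solvent sphere.  Since the
    points are equal-area, an isolated atom is exact up to floating
    point: ``4*pi*(r+probe)**2``.
    """
    if n_points < 16:
        raise ValueError("n_points must be >= 16")
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    n = len(coords)
    unit = sphere_points(n_points)
    ext = radii_values + probe
    tree = cKDTree(coords)
    out = np.zeros(n)
    max_ext = ext.max()
    for i in range(n):
        pts = coords[i] + ext[i] * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], ext[i] + max_ext)
                     if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            accessible &= d2 > ext[j] ** 2
        out[i] = accessible.mean() * 4 * np.pi * ext[i] ** 2
    return out


def sasa_per_residue(
    model: StructureModel,
    probe: float = PROBE_RADIUS,
    n_points: int = 960,
    radii: dict[str, float] | None = None,
    max_asa: dict[str, float] | None = None,
    include_het: bool = True,
) -> pd.DataFrame:
    """Absolute and relative (0-100) SASA per protein residue.

    Hydrogens are ignored; HETATM groups occlude by default but their own
    area is not reported.  Relative SASA is capped at 100.
    """
    radii = radii or VDW_RADII
    max_asa = max_asa or MAX_ASA
    coords, rvals, owner = [], [], []
    for idx, res in enumerate(model.residues):
        for atom in res.atoms.values():
            if atom.element == "H":
                continue
            coords.append(atom.coord)
            rvals.append(_atom_radius(atom.element, radii))
            owner.append(idx)
    n_protein = len(coords)
    if include_het:
        for atoms in model.het_groups.values():
            for atom in atoms:
                if atom.element == "H":
                    continue
                coords.append(atom.coord)
                rvals.append(_atom_radius(atom.element, radii))
                owner.append(-1)
    areas = sasa_atoms(np.array(coords), np.array(rvals), probe, n_points)

    per_res = np.zeros(len(model.residues))
    for area, idx in zip(areas[:n_protein], owner[:n_protein]):
        per_res[idx] += area
    rows = []
    for res, area in zip(model.residues, per_res):
        ref = max_asa.get(res.one_letter)
        rel = min(100.0, 100.0 * area / ref) if ref else np.nan
        rows.append((res.chain, res.resseq, res.icode, res.one_letter, area, rel))
    return pd.DataFrame(
        rows, columns=["chain", "position", "icode", "aa", "sasa_abs", "sasa_rel"]
    )


# ---------------------------------------------------------------------------
# Distance features


def mean_distance_to_group(ca_coord: np.ndarray, group: np.ndarray) -> float:
    """Arithmetic mean of Euclidean distances from a Cα to a set of atoms."""
    group = np.asarray(group, dtype=float)
    if group.size == 0:
        raise ValueError("empty atom group")
    return float(np.linalg.norm(group - np.asarray(ca_coord), axis=1).mean())


def interface_residues(
    model: StructureModel, chain_a: str, chain_b: str, contact_cutoff: float = 5.0
) -> set[tuple[str, int, str]]:
    """Residues with any inter-chain heavy-atom pair within the cutoff."""
    res_a = model.chain_residues(chain_a)
    res_b = model.chain_residues(chain_b)
    if not res_a or not res_b:
        raise ValueError("both chains must be present")
    out: set[tuple[str, int, str]] = set()
    coords_b = [(r, r.heavy_coords()) for r in res_b]
    trees_b = [(r, cKDTree(c)) for r, c in coords_b if len(c)]
    for ra in res_a:
        ca_coords = ra.heavy_coords()
        if not len(ca_coords):
            continue
        tree_a = cKDTree(ca_coords)
        for rb, tree_b in trees_b:
            hits = tree_a.query_ball_tree(tree_b, contact_cutoff)
            if any(len(h) for h in hits):
                out.add(ra.key)
                out.add(rb.key)
    return out


def distance_to_interface(
    model: StructureModel, interface: set[tuple[str, int, str]]
) -> dict[tuple[str, int, str], float]:
    """Cα distance from every residue to the nearest interface Cα.

    Interface residues get 0 by definition; residues lacking a Cα are
    omitted (flagged upstream).
    """
    iface_ca = [
        r.ca().coord for r in model.residues if r.key in interface and r.ca()
    ]
    if not iface_ca:
        raise ValueError("no interface residue with a Cα")
    iface_ca = np.array(iface_ca)
    out = {}
    for res in model.residues:
        ca = res.ca()
        if ca is None:
            continue
        if res.key in interface:
            out[res.key] = 0.0
        else:
            out[res.key] = float(
                np.linalg.norm(iface_ca - ca.coord, axis=1).min()
            )
    return out


def active_site_center(
    model: StructureModel, spec: str | np.ndarray
) -> np.ndarray:
    """Resolve the catalytic-center definition to a 3D point.

    ``spec`` is either an explicit coordinate triple or the residue name
    of a HETATM group (e.g. a bound substrate analogue) whose centroid
    defines the center.
    """
    if isinstance(spec, str):
        atoms = model.het_groups.get(spec)
        if not atoms:
            raise ValueError(f"no HETATM group named {spec!r}")
        return np.mean([a.coord for a in atoms], axis=0)
    center = np.asarray(spec, dtype=float)
    if center.shape != (3,):
        raise ValueError("explicit active-site spec must be a 3-vector")
    return center


def distance_to_active_site(ca_coord: np.ndarray, center: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(ca_coord) - np.asarray(center)))


# ---------------------------------------------------------------------------
# Property scales


def residue_scales(
    aa: str, scales: dict[str, dict[str, float]] | None = None
) -> dict[str, float]:
    scales = scales or DEFAULT_SCALES
    out = {}
    for name, table in scales.items():
        if aa not in table:
            raise ValueError(f"unknown amino acid {aa!r} for scale {name}")
        out[name] = table[aa]
    return out


def delta_scales(
    wt_aa: str, mut_aa: str, scales: dict[str, dict[str, float]] | None = None
) -> dict[str, float]:
    """scale(mut) - scale(wt) for each property (sign convention: mutant
    minus wild type; negate for the opposite convention)."""
    wt = residue_scales(wt_aa, scales)
    mut = residue_scales(mut_aa, scales)
    return {name: mut[name] - wt[name] for name in wt}


# ---------------------------------------------------------------------------
# Assembled feature table


def build_feature_table(
    model: StructureModel,
    chain: str,
    partner_chain: str | None = None,
    cofactor: str | None = "FAD",
    active_site: str | np.ndarray | None = None,
    contact_cutoff: float = 5.0,
    n_points: int = 960,
    conservation: pd.DataFrame | None = None,
    scales: dict[str, dict[str, float]] | None = None,
) -> pd.DataFrame:
    """One row per residue of ``chain`` with every structural feature.

    ``conservation``, if given, is a frame with columns ``position`` and
    ``cons`` (0-100) joined on PDB residue number.
    """
    sasa = sasa_per_residue(model, n_points=n_points)
    sasa = sasa[sasa["chain"] == chain].set_index("position")

    iface_d = None
    if partner_chain is not None:
        iface = interface_residues(model, chain, partner_chain, contact_cutoff)
        iface_d = distance_to_interface(model, iface)

    fad_coords = None
    if cofactor is not None and cofactor in model.het_groups:
        fad_coords = np.array([a.coord for a in model.het_groups[cofactor]])

    center = active_site_center(model, active_site) if active_site is not None else None

    rows = []
    for res in model.chain_residues(chain):
        ca = res.ca()
        row: dict[str, object] = {
            "position": res.resseq,
            "aa": res.one_letter,
            "has_ca": ca is not None,
            "bfactor": ca.bfactor if ca else np.nan,
            "sasa_rel": sasa["sasa_rel"].get(res.resseq, np.nan),
            "sasa_abs": sasa["sasa_abs"].get(res.resseq, np.nan),
        }
        row["d_fad"] = (
            mean_distance_to_group(ca.coord, fad_coords)
            if ca is not None and fad_coords is not None else np.nan
        )
        row["d_interface"] = (
            iface_d.get(res.key, np.nan) if iface_d is not None else np.nan
        )
        row["d_active"] = (
            distance_to_active_site(ca.coord, center)
            if ca is not None and center is not None else np.nan
        )
        if res.one_letter in THREE_TO_ONE.values():
            row.update(residue_scales(res.one_letter, scales))
        rows.append(row)
    table = pd.DataFrame(rows)
    if conservation is not None:
        table = table.merge(conservation[["position", "cons"]], on="position",
                            how="left")
    return table
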