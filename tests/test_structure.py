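"""Structural features: PDB parsing, Shrake-Rupley SASA, distance
features, interface detection and property scales."""

import numpy as np
import pytest

from epseq import structure as struct
from epseq.structure import (
    active_site_center,
    build_feature_table,
    delta_scales,
    distance_to_active_site,
    distance_to_interface,
    interface_residues,
    mean_distance_to_group,
    parse_pdb,
    residue_scales,
    sasa_atoms,
    sasa_per_residue,
    sphere_points,
)

from conftest import pdb_atom_line


def ala_residue(serial0, chain, resseq, offset, bfactor=10.0):
    """Minimal alanine backbone + CB at a translated origin."""
    ox, oy, oz = offset
    return [
        pdb_atom_line(serial0, "N", "ALA", chain, resseq,
                      (ox, oy, oz), element="N", bfactor=bfactor),
        pdb_atom_line(serial0 + 1, "CA", "ALA", chain, resseq,
                      (ox + 1.5, oy, oz), element="C", bfactor=bfactor),
        pdb_atom_line(serial0 + 2, "C", "ALA", chain, resseq,
                      (ox + 2.5, oy + 1.0, oz), element="C", bfactor=bfactor),
        pdb_atom_line(serial0 + 3, "O", "ALA", chain, resseq,
                      (ox + 3.5, oy + 1.0, oz + 0.5), element="O",
                      bfactor=bfactor),
        pdb_atom_line(serial0 + 4, "CB", "ALA", chain, resseq,
                      (ox + 1.5, oy - 1.5, oz), element="C", bfactor=bfactor),
    ]


class TestParsePdb:
    def test_single_residue_round_trip(self, write_pdb):
        path = write_pdb(ala_residue(1, "A", 1, (0, 0, 0), bfactor=22.5))
        model = parse_pdb(path)
        assert len(model.residues) == 1
        res = model.residues[0]
        assert res.resname == "ALA" and res.one_letter == "A"
        assert res.ca().coord == pytest.approx([1.5, 0.0, 0.0])
        assert res.ca().bfactor == 22.5

    def test_altloc_resolves_to_highest_occupancy(self, write_pdb):
        lines = [
            pdb_atom_line(1, "CA", "ALA", "A", 1, (0, 0, 0), occupancy=0.6,
                          altloc="A", element="C"),
            pdb_atom_line(2, "CA", "ALA", "A", 1, (9, 9, 9), occupancy=0.4,
                          altloc="B", element="C"),
        ]
        model = parse_pdb(write_pdb(lines))
        assert model.residues[0].ca().coord == pytest.approx([0, 0, 0])

    def test_two_chains_reported_separately(self, write_pdb):
        lines = ala_residue(1, "A", 1, (0, 0, 0)) + ala_residue(6, "B", 1, (30, 0, 0))
        model = parse_pdb(write_pdb(lines))
        assert model.chains == ["A", "B"]
        assert len(model.chain_residues("A")) == 1

    def test_hetatm_groups_collected(self, write_pdb):
        lines = ala_residue(1, "A", 1, (0, 0, 0)) + [
            pdb_atom_line(10, "N1", "FAD", "A", 500, (5, 5, 5),
                          element="N", record="HETATM"),
            pdb_atom_line(11, "C2", "FAD", "A", 500, (6, 5, 5),
                          element="C", record="HETATM"),
        ]
        model = parse_pdb(write_pdb(lines))
        assert set(model.het_groups) == {"FAD"}
        assert len(model.het_groups["FAD"]) == 2

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("END\n")
        with pytest.raises(ValueError):
            parse_pdb(path)


class TestSasa:
    def test_isolated_atom_matches_closed_form(self):
        r = 1.7
        area = sasa_atoms(np.array([[0.0, 0.0, 0.0]]), np.array([r]),
                          probe=1.4, n_points=960)
        assert area[0] == pytest.approx(4 * np.pi * (r + 1.4) ** 2, rel=0.01)

    def test_fully_enclosed_atom_has_zero_sasa(self):
        dirs = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    if (dx, dy, dz) != (0, 0, 0):
                        v = np.array([dx, dy, dz], dtype=float)
                        dirs.append(v / np.linalg.norm(v))
        coords = np.vstack([[0.0, 0.0, 0.0], dirs])
        areas = sasa_atoms(coords, np.full(len(coords), 1.7),
                           probe=1.4, n_points=960)
        assert areas[0] == 0.0

    def test_two_atom_overlap_matches_cap_formula(self):
        """Accessible area of two overlapping solvent spheres has a
        closed-form spherical-cap solution."""
        r1, r2, probe, d = 1.7, 1.52, 1.4, 2.0
        R1, R2 = r1 + probe, r2 + probe
        coords = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
        areas = sasa_atoms(coords, np.array([r1, r2]), probe, n_points=2000)
        cos1 = (d ** 2 + R1 ** 2 - R2 ** 2) / (2 * d * R1)
        cap1 = 2 * np.pi * R1 ** 2 * (1 - cos1)
        expected1 = 4 * np.pi * R1 ** 2 - cap1
        assert areas[0] == pytest.approx(expected1, rel=0.01)

    def test_matches_independent_shrake_rupley(self, write_pdb):
        """Cross-check against Biopython's Shrake-Rupley on the same
        radii (different deterministic point sets, so a few percent)."""
        from Bio.PDB import PDBParser
        from Bio.PDB.SASA import ShrakeRupley

        lines = (ala_residue(1, "A", 1, (0, 0, 0))
                 + ala_residue(6, "A", 2, (3.8, 0, 0)))
        path = write_pdb(lines)
        model = parse_pdb(path)
        mine = sasa_per_residue(model, n_points=960)

        bio = PDBParser(QUIET=True).get_structure("m", str(path))
        sr = ShrakeRupley(probe_radius=1.4, n_points=960,
                          radii_dict={"C": 1.70, "N": 1.55, "O": 1.52})
        sr.compute(bio[0], level="R")
        theirs = [r.sasa for r in bio[0].get_residues()]
        assert mine["sasa_abs"].to_numpy() == pytest.approx(theirs, rel=0.03)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="n_points"):
            sasa_atoms(np.zeros((1, 3)), np.array([1.7]), n_points=8)

    def test_relative_sasa_capped_and_bounded(self, write_pdb):
        model = parse_pdb(write_pdb(ala_residue(1, "A", 1, (0, 0, 0))))
        table = sasa_per_residue(model)
        assert ((table["sasa_rel"] >= 0) & (table["sasa_rel"] <= 100)).all()

    def test_sphere_points_are_unit_and_deterministic(self):
        pts = sphere_points(500)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)
        assert np.allclose(pts, sphere_points(500))


class TestDistances:
    def test_mean_distance_arithmetic(self):
        assert mean_distance_to_group(
            np.zeros(3), np.array([[3, 0, 0], [0, 4, 0]])
        ) == 3.5

    def test_single_atom_group(self):
        assert mean_distance_to_group(
            np.zeros(3), np.array([[0, 0, 7.5]])
        ) == 7.5

    def test_random_group_matches_loop_oracle(self):
        rng = np.random.default_rng(0)
        ca = rng.normal(size=3)
        group = rng.normal(size=(10, 3))
        expected = sum(
            float(np.sqrt(((g - ca) ** 2).sum())) for g in group
        ) / 10
        assert mean_distance_to_group(ca, group) == pytest.approx(expected)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mean_distance_to_group(np.zeros(3), np.empty((0, 3)))

    def test_active_site_identity_and_construction(self):
        assert distance_to_active_site([0, 0, 7.5], [0, 0, 0]) == 7.5
        assert distance_to_active_site([1, 2, 3], [1, 2, 3]) == 0.0

    def test_ligand_centroid_oracle(self, write_pdb):
        coords = [(0, 0, 0), (2, 0, 0), (0, 2, 0), (0, 0, 2)]
        lines = ala_residue(1, "A", 1, (10, 0, 0)) + [
            pdb_atom_line(10 + i, f"C{i}", "LIG", "A", 900, c,
                          element="C", record="HETATM")
            for i, c in enumerate(coords)
        ]
        model = parse_pdb(write_pdb(lines))
        center = active_site_center(model, "LIG")
        assert center == pytest.approx(np.mean(coords, axis=0))


class TestInterface:
    def dimer(self, write_pdb, gap=4.0):
        lines = []
        serial = 1
        for i in range(4):
            lines += ala_residue(serial, "A", i + 1, (0, i * 6.0, 0))
            serial += 5
        for i in range(4):
            lines += ala_residue(serial, "B", i + 1, (gap + 3.0, i * 6.0, 0))
            serial += 5
        return parse_pdb(write_pdb(lines))

    def test_contacting_residues_are_interface(self, write_pdb):
        model = self.dimer(write_pdb, gap=1.0)
        iface = interface_residues(model, "A", "B", contact_cutoff=5.0)
        d = distance_to_interface(model, iface)
        for key in iface:
            assert d[key] == 0.0

    def test_distant_chains_have_no_interface(self, write_pdb):
        model = self.dimer(write_pdb, gap=50.0)
        assert not interface_residues(model, "A", "B", contact_cutoff=5.0)

    def test_interface_matches_brute_force_scan(self, write_pdb):
        """Synthetic dimer: the detected set equals an exhaustive
        all-pairs heavy-atom distance scan."""
        rng = np.random.default_rng(1)
        lines, serial = [], 1
        offsets_a = rng.uniform(0, 15, size=(6, 3))
        offsets_b = rng.uniform(3, 18, size=(6, 3))
        for i, off in enumerate(offsets_a):
            lines += ala_residue(serial, "A", i + 1, tuple(off))
            serial += 5
        for i, off in enumerate(offsets_b):
            lines += ala_residue(serial, "B", i + 1, tuple(off))
            serial += 5
        model = parse_pdb(write_pdb(lines))
        cutoff = 5.0
        iface = interface_residues(model, "A", "B", cutoff)

        expected = set()
        for ra in model.chain_residues("A"):
            for rb in model.chain_residues("B"):
                pa, pb = ra.heavy_coords(), rb.heavy_coords()
                dmin = np.sqrt(
                    ((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1)
                ).min()
                if dmin <= cutoff:
                    expected.add(ra.key)
                    expected.add(rb.key)
        assert iface == expected

    def test_distance_to_interface_by_construction(self, write_pdb):
        lines = (
            ala_residue(1, "A", 1, (0, 0, 0))
            + ala_residue(6, "A", 2, (0, 20.0, 0))
            + ala_residue(11, "B", 1, (4.0, 0, 0))
        )
        model = parse_pdb(write_pdb(lines))
        iface = interface_residues(model, "A", "B", 5.0)
        d = distance_to_interface(model, iface)
        assert d[("A", 2, "")] == pytest.approx(20.0)

    def test_single_chain_rejected(self, write_pdb):
        model = parse_pdb(write_pdb(ala_residue(1, "A", 1, (0, 0, 0))))
        with pytest.raises(ValueError, match="chains"):
            interface_residues(model, "A", "B")


class TestScales:
    def test_lookup_returns_table_values(self):
        scales = residue_scales("A")
        assert scales["hydrophobicity"] == struct.HYDROPHOBICITY["A"]
        assert scales["bulkiness"] == struct.BULKINESS["A"]

    def test_delta_zero_for_identity(self):
        assert all(v == 0 for v in delta_scales("V", "V").values())

    def test_delta_antisymmetry(self):
        fwd = delta_scales("A", "V")
        rev = delta_scales("V", "A")
        for name in fwd:
            assert fwd[name] == pytest.approx(-rev[name])

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError, match="unknown amino acid"):
            residue_scales("B")


class TestRigidMotionInvariance:
    def _rotated(self, lines_fn, write_pdb):
        rng = np.random.default_rng(7)
        # random rotation via QR decomposition
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        shift = np.array([5.0, -3.0, 11.0])
        return q, shift

    def test_sasa_and_distances_invariant(self, write_pdb):
        base = (ala_residue(1, "A", 1, (0, 0, 0))
                + ala_residue(6, "A", 2, (3.8, 0, 0))
                + ala_residue(11, "B", 1, (7.0, 0, 0)))
        model = parse_pdb(write_pdb(base, "base.pdb"))
        q, shift = self._rotated(None, None)
        rotated = parse_pdb(write_pdb(base, "rot.pdb"))
        for res in rotated.residues:
            for atom in res.atoms.values():
                atom.coord = q @ atom.coord + shift

        s0 = sasa_per_residue(model, n_points=4000)["sasa_abs"].to_numpy()
        s1 = sasa_per_residue(rotated, n_points=4000)["sasa_abs"].to_numpy()
        assert s1 == pytest.approx(s0, rel=0.005)

        i0 = interface_residues(model, "A", "B", 5.0)
        i1 = interface_residues(rotated, "A", "B", 5.0)
        assert i0 == i1
        d0 = distance_to_interface(model, i0)
        d1 = distance_to_interface(rotated, i1)
        for key in d0:
            assert d1[key] == pytest.approx(d0[key], abs=1e-6)


def test_feature_table_assembles_everything(write_pdb):
    import pandas as pd

    lines = (
        ala_residue(1, "A", 1, (0, 0, 0), bfactor=15.0)
        + ala_residue(6, "A", 2, (3.8, 0, 0), bfactor=30.0)
        + ala_residue(11, "B", 1, (7.0, 0, 0))
        + [pdb_atom_line(16, "N1", "FAD", "A", 500, (0, 10, 0),
                         element="N", record="HETATM")]
    )
    model = parse_pdb(write_pdb(lines))
    cons = pd.DataFrame({"position": [1, 2], "cons": [100.0, 40.0]})
    table = build_feature_table(
        model, chain="A", partner_chain="B", cofactor="FAD",
        active_site=np.array([0.0, 10.0, 0.0]), conservation=cons,
        n_points=240,
    )
    assert len(table) == 2
    assert table.loc[0, "bfactor"] == 15.0  # matches the written value
    assert table.loc[1, "bfactor"] == 30.0
    assert (table["d_fad"] > 0).all()
    assert table.loc[0, "cons"] == 100.0
    assert {"hydrophobicity", "bulkiness", "polarity"} <= set(table.columns)
    assert table["sasa_rel"].between(0, 100).all()
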