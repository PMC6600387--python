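"""Anchor-site descriptors: SASA oracles, torsion conventions, binning."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from covbench.datamodel import AnchorResidue, BenchmarkEntry, LigandPose
from covbench.site_features import (
    accuracy_by_feature,
    anchor_dihedral,
    anchor_sasa,
    dihedral_angle,
    shrake_rupley_sasa,
)
from conftest import CYS_ATOMS


def _fib_shell(n: int, radius: float, center) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * np.arange(n)
    z = 1.0 - 2.0 * k / n
    r = np.sqrt(1.0 - z * z)
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return center + radius * pts


def _entry_with_receptor(extra_atoms=None) -> BenchmarkEntry:
    rows = [("A", 25, "CYS", n, e, *xyz) for n, e, xyz in CYS_ATOMS]
    if extra_atoms is not None:
        rows += [("A", 99, "SHL", f"X{i}", "C", *p)
                 for i, p in enumerate(extra_atoms)]
    receptor = pd.DataFrame(rows, columns=["chain", "resnum", "resname",
                                           "name", "element", "x", "y", "z"])
    anchor = AnchorResidue(
        chain="A", residue_number=25, residue_name="CYS", link_atom="SG",
        atoms={n: np.asarray(xyz) for n, _, xyz in CYS_ATOMS})
    ligand = LigandPose(elements=("C",) * 5,
                        coords=np.arange(15.0).reshape(5, 3))
    return BenchmarkEntry(entry_id="sasa", anchor=anchor,
                          reference_ligand=ligand, receptor_atoms=receptor)


class TestShrakeRupley:
    def test_isolated_atom_is_full_sphere(self):
        area = shrake_rupley_sasa(np.zeros((1, 3)), [1.87], probe=1.4)
        assert area[0] == pytest.approx(4 * math.pi * (1.87 + 1.4) ** 2,
                                        rel=1e-6)

    def test_two_sphere_overlap_matches_spherical_cap(self):
        # analytic: buried cap area on sphere 1 = 2 pi R1 (R1 - x),
        # x = (d^2 + R1^2 - R2^2) / (2 d)
        r1, r2, probe, d = 1.87, 1.40, 1.4, 2.8
        R1, R2 = r1 + probe, r2 + probe
        coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        areas = shrake_rupley_sasa(coords, [r1, r2], probe=probe,
                                   n_points=8000)
        x = (d * d + R1 * R1 - R2 * R2) / (2 * d)
        expected = 4 * math.pi * R1 ** 2 - 2 * math.pi * R1 * (R1 - x)
        assert areas[0] == pytest.approx(expected, rel=0.01)

    def test_default_density_matches_dense_oracle(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 6, size=(8, 3))
        radii = rng.uniform(1.4, 1.9, size=8)
        coarse = shrake_rupley_sasa(coords, radii, n_points=960)
        dense = shrake_rupley_sasa(coords, radii, n_points=10000)
        assert np.allclose(coarse, dense, atol=1.5)   # A^2 per atom

    def test_agrees_with_biopython_implementation(self):
        from Bio.PDB.SASA import ShrakeRupley
        from Bio.PDB.StructureBuilder import StructureBuilder

        rng = np.random.default_rng(12)
        coords = rng.uniform(0, 8, size=(10, 3))
        radius = 1.87
        sb = StructureBuilder()
        sb.init_structure("x")
        sb.init_model(0)
        sb.init_chain("A")
        sb.init_seg(" ")
        for i, xyz in enumerate(coords):
            sb.init_residue(f"R", " ", i + 1, " ")
            sb.init_atom("C", xyz.astype(np.float64), 0.0, 1.0, " ",
                         "C", i + 1, "C")
        structure = sb.get_structure()
        calc = ShrakeRupley(probe_radius=1.4, n_points=960,
                            radii_dict={"C": radius})
        calc.compute(structure, level="A")
        theirs = np.array([a.sasa for a in structure.get_atoms()])
        ours = shrake_rupley_sasa(coords, [radius] * 10, n_points=960)
        assert np.allclose(ours, theirs, atol=1.5)


class TestAnchorSasa:
    def test_exposed_residue_positive(self):
        entry = _entry_with_receptor()
        assert anchor_sasa(entry) > 50.0

    def test_fully_buried_residue_near_zero(self):
        center = np.mean([xyz for _, _, xyz in CYS_ATOMS], axis=0)
        shell = np.vstack([_fib_shell(500, 7.0, center),
                           _fib_shell(300, 5.5, center)])
        entry = _entry_with_receptor(extra_atoms=shell)
        assert anchor_sasa(entry) == pytest.approx(0.0, abs=1.0)

    def test_occlusion_monotonicity(self):
        center = np.mean([xyz for _, _, xyz in CYS_ATOMS], axis=0)
        shells = [None,
                  _fib_shell(100, 8.0, center),
                  np.vstack([_fib_shell(100, 8.0, center),
                             _fib_shell(200, 6.0, center)])]
        values = [anchor_sasa(_entry_with_receptor(extra_atoms=s))
                  for s in shells]
        assert values[0] >= values[1] >= values[2]

    def test_probe_growth_increases_burial_of_pocket(self):
        center = np.mean([xyz for _, _, xyz in CYS_ATOMS], axis=0)
        shell = _fib_shell(250, 6.5, center)
        entry = _entry_with_receptor(extra_atoms=shell)
        open_frac = []
        for probe in (1.4, 2.8):
            exposed = anchor_sasa(entry, probe=probe)
            alone = anchor_sasa(_entry_with_receptor(), probe=probe)
            open_frac.append(exposed / alone)
        assert open_frac[1] <= open_frac[0] + 1e-9

    def test_missing_side_chain_atom_named_in_error(self):
        entry = _entry_with_receptor()
        rec = entry.receptor_atoms
        entry.receptor_atoms = rec[rec["name"] != "SG"]
        with pytest.raises(ValueError, match="SG"):
            anchor_sasa(entry)


class TestDihedral:
    @staticmethod
    def _constructed(theta_deg: float) -> list[np.ndarray]:
        # torsion built by rotating the distal atom about the central axis
        theta = math.radians(theta_deg)
        p1 = np.array([0.0, 0.0, 0.0])
        p2 = np.array([0.0, 0.0, 1.5])
        p0 = np.array([1.0, 0.0, -0.5])
        p3 = np.array([math.cos(theta), math.sin(theta), 2.0])
        return [p0, p1, p2, p3]

    def test_constructed_sixty_degrees(self):
        pts = self._constructed(60.0)
        got = dihedral_angle(*pts)
        assert abs(got) == pytest.approx(60.0, abs=1e-9)

    def test_agrees_with_biopython_on_random_points(self):
        from Bio.PDB.vectors import Vector, calc_dihedral
        rng = np.random.default_rng(21)
        for _ in range(50):
            pts = rng.normal(size=(4, 3)) * 3
            ours = dihedral_angle(*pts)
            theirs = math.degrees(calc_dihedral(*(Vector(*p) for p in pts)))
            assert ours == pytest.approx(theirs, abs=1e-8)

    def test_mirror_image_flips_sign(self):
        pts = self._constructed(60.0)
        mirrored = [p * np.array([-1.0, 1.0, 1.0]) for p in pts]
        assert dihedral_angle(*mirrored) == pytest.approx(
            -dihedral_angle(*pts), abs=1e-9)

    def test_boundary_reported_as_plus_180(self):
        got = dihedral_angle(*self._constructed(180.0))
        assert got == pytest.approx(180.0, abs=1e-9)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(6)
        pts = self._constructed(-73.0)
        base = dihedral_angle(*pts)
        # random rotation (QR of a Gaussian matrix) + translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        shift = rng.normal(size=3) * 10
        moved = [q @ p + shift for p in pts]
        assert dihedral_angle(*moved) == pytest.approx(base, abs=1e-8)

    def test_collinear_geometry_rejected(self):
        pts = [np.array([float(i), 0, 0]) for i in range(4)]
        with pytest.raises(ValueError, match="degenerate|collinear"):
            dihedral_angle(*pts)

    def test_anchor_dihedral_reads_residue_atoms(self):
        entry = _entry_with_receptor()
        value = anchor_dihedral(entry)
        assert -180.0 < value <= 180.0


class TestAccuracyByFeature:
    def test_planted_sasa_gradient_recovered(self):
        rng = np.random.default_rng(14)
        rows, desc = [], []
        for i in range(60):
            sasa = rng.uniform(0, 30)
            s1 = 1.0 + 0.1 * sasa + rng.normal(0, 0.05)
            rows.append({"tool_id": "A", "entry_id": f"e{i}", "s1": s1})
            desc.append({"entry_id": f"e{i}", "sasa": sasa, "dihedral": 0.0})
        table = accuracy_by_feature(pd.DataFrame(rows), pd.DataFrame(desc),
                                    "sasa")
        medians = table.dropna(subset=["median_s1"])["median_s1"].tolist()
        assert medians == sorted(medians)

    def test_single_bin_equals_overall_median(self):
        rows = [{"tool_id": "A", "entry_id": f"e{i}", "s1": float(i)}
                for i in range(5)]
        desc = [{"entry_id": f"e{i}", "sasa": 3.0} for i in range(5)]
        table = accuracy_by_feature(pd.DataFrame(rows), pd.DataFrame(desc),
                                    "sasa", bins=10.0)
        filled = table.dropna(subset=["median_s1"])
        assert len(filled) == 1
        assert filled["median_s1"].iloc[0] == pytest.approx(2.0)

    def test_kinase_domain_counts_recovered(self):
        counts = {"Front pocket": 31, "DFG-3": 14, "P-loop": 9}
        rows, desc = [], []
        i = 0
        for domain, n in counts.items():
            for _ in range(n):
                rows.append({"tool_id": "A", "entry_id": f"e{i}", "s1": 1.0})
                desc.append({"entry_id": f"e{i}", "sasa": 1.0,
                             "dihedral": 0.0, "kinase_domain": domain})
                i += 1
        table = accuracy_by_feature(pd.DataFrame(rows), pd.DataFrame(desc),
                                    "kinase_domain")
        got = dict(zip(table["bin"], table["n"]))
        assert {k: got[k] for k in counts} == counts

    def test_empty_bins_are_missing_not_zero(self):
        rows = [{"tool_id": "A", "entry_id": "e0", "s1": 1.0}]
        desc = [{"entry_id": "e0", "sasa": 25.0}]
        table = accuracy_by_feature(pd.DataFrame(rows), pd.DataFrame(desc),
                                    "sasa")
        empty = table[table["n"] == 0]
        assert empty["median_s1"].isna().all()
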