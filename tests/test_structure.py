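"""Structure parsing, solvent accessibility, surface calling, patches and
the geometric attributes, checked against analytic and brute-force oracles."""

import math

import numpy as np
import pytest
from Bio.PDB.SASA import ATOMIC_RADII
from scipy.spatial.transform import Rotation

from epitopatch import fixtures
from epitopatch.structure import (AccessibilityRecord, AntigenStructure, Atom,
                                  ChainNotFoundError, EmptyStructureError,
                                  PDBFormatError, Residue, ResidueId,
                                  assign_secondary_structure, compute_sasa,
                                  contact_number, enumerate_patches,
                                  identify_surface_residues, parse_structure,
                                  plane_rmsd, planarity_score,
                                  representative_point, _raw_sasa)

from conftest import random_point_structure

PROBE = 1.2

ONE_ATOM_PDB = ("ATOM      1  CA  ALA A   1       "
                "0.000   0.000   0.000  1.00  0.00           C\nEND\n")


def _atom_pdb(coords, element="C", name="CA"):
    lines = []
    for i, (x, y, z) in enumerate(coords, 1):
        lines.append(f"ATOM  {i:>5} {name:^4} ALA A{i:>4}    "
                     f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
                     f"{element:>2}")
    return "\n".join(lines) + "\nEND\n"


class TestParsing:
    def test_minimal_single_atom(self):
        s = parse_structure(ONE_ATOM_PDB)
        assert s.chains == ["A"]
        assert len(s) == 1
        assert len(s.residues[0].atoms) == 1

    def test_generator_round_trip(self, helix_fixture):
        s = parse_structure(helix_fixture.pdb_text)
        assert len(s) == 30
        assert sum(len(r.atoms) for r in s.residues) == \
            helix_fixture.atoms_emitted

    def test_chain_filter(self, two_chain_fixture):
        s = parse_structure(two_chain_fixture.pdb_text, "A")
        assert {r.id.chain for r in s.residues} == {"A"}

    def test_missing_chain_raises(self, two_chain_fixture):
        with pytest.raises(ChainNotFoundError):
            parse_structure(two_chain_fixture.pdb_text, "Z")

    def test_garbage_raises_format_error(self):
        with pytest.raises((PDBFormatError, EmptyStructureError)):
            parse_structure("not a PDB\nat all\n")

    def test_waters_dropped(self):
        text = ONE_ATOM_PDB.replace("END", "") + (
            "HETATM    2  O   HOH A 101       9.000   0.000   0.000"
            "  1.00  0.00           O\nEND\n")
        assert len(parse_structure(text)) == 1


class TestSasa:
    def test_isolated_atom_matches_analytic_sphere(self):
        s = parse_structure(ONE_ATOM_PDB)
        total, _ = _raw_sasa(s, PROBE, 960)[ResidueId("A", 1)]
        analytic = 4 * math.pi * (ATOMIC_RADII["C"] + PROBE) ** 2
        assert total == pytest.approx(analytic, rel=0.01)

    def test_non_overlapping_atoms_each_full_sphere(self):
        r = ATOMIC_RADII["C"]
        s = parse_structure(_atom_pdb([(0, 0, 0), (2 * (r + PROBE) + 0.5, 0, 0)]))
        analytic = 4 * math.pi * (r + PROBE) ** 2
        raw = _raw_sasa(s, PROBE, 960)
        for rid in s.residue_ids():
            assert raw[rid][0] == pytest.approx(analytic, rel=0.01)

    def test_enclosed_atom_is_buried(self):
        # dense shell of atoms on a 3 A sphere around the centre atom
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(80, 3))
        pts = 3.0 * pts / np.linalg.norm(pts, axis=1, keepdims=True)
        s = parse_structure(_atom_pdb([(0.0, 0.0, 0.0)] + pts.tolist()))
        total, _ = _raw_sasa(s, PROBE, 960)[ResidueId("A", 1)]
        assert total < 1e-6

    def test_rigid_motion_invariance(self, helix_fixture):
        s = helix_fixture.structure
        rot = Rotation.from_euler("xyz", [31, -54, 117], degrees=True).as_matrix()
        shift = np.array([5.0, -3.0, 11.0])
        moved = AntigenStructure([
            Residue(r.id, r.restype,
                    [Atom(a.name, a.element, tuple(rot @ a.xyz + shift))
                     for a in r.atoms])
            for r in s.residues])
        rec_a = compute_sasa(s)
        rec_b = compute_sasa(moved)
        for rid in s.residue_ids():
            # sampling-grid tolerance: a few A^2 on ~100 A^2 residues
            assert rec_b[rid].sasa_total == pytest.approx(
                rec_a[rid].sasa_total, abs=4.0)


class TestSurface:
    def _rec(self, rid, rel):
        return AccessibilityRecord(rid, "ALA", 10.0, 5.0, rel, PROBE)

    def test_threshold_is_strict(self):
        rids = [ResidueId("A", i) for i in range(3)]
        records = {rids[0]: self._rec(rids[0], 0.0),
                   rids[1]: self._rec(rids[1], 0.06),
                   rids[2]: self._rec(rids[2], 0.0601)}
        assert identify_surface_residues(records) == [rids[2]]

    def test_planted_exposure_recovered(self, globule_fixture):
        records = compute_sasa(globule_fixture.structure)
        assert identify_surface_residues(records) == globule_fixture.surface
        # the packed lattice really buries a core
        assert len(globule_fixture.surface) < len(globule_fixture.structure)

    def test_monotone_in_threshold(self, globule_fixture):
        records = globule_fixture.records
        prev = None
        for thr in (0.0, 0.06, 0.2, 0.5, 1.0):
            cur = set(identify_surface_residues(records, thr))
            if prev is not None:
                assert cur <= prev
            prev = cur


class TestPatches:
    def test_forced_membership_when_surface_equals_patch_size(self):
        rng = np.random.default_rng(3)
        s = random_point_structure(rng, 20)
        surface = s.residue_ids()
        patches = enumerate_patches(s, surface, patch_size=20)
        assert len(patches) == 20
        for p in patches:
            assert set(p.members) == set(surface)

    @pytest.mark.parametrize("seed", range(5))
    def test_membership_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(25, 45))
        s = random_point_structure(rng, n)
        surface = s.residue_ids()
        patches = enumerate_patches(s, surface, patch_size=20)
        assert len(patches) == n
        pts = {rid: representative_point(s.residue(rid)) for rid in surface}
        for p in patches:
            dists = sorted(
                (np.linalg.norm(pts[rid] - pts[p.center]), rid)
                for rid in surface)
            expected = {rid for _, rid in dists[:min(20, n)]}
            assert set(p.members) == expected
            assert p.center in p.members

    def test_too_few_surface_residues_rejected(self):
        rng = np.random.default_rng(1)
        s = random_point_structure(rng, 5)
        with pytest.raises(EmptyStructureError):
            enumerate_patches(s, s.residue_ids()[:2])


class TestContactNumber:
    def test_single_residue(self):
        s = parse_structure(ONE_ATOM_PDB)
        assert contact_number(s, ResidueId("A", 1)) == 0

    def test_just_outside_cutoff(self):
        s = parse_structure(_atom_pdb([(0, 0, 0), (10.001, 0, 0)]))
        for rid in s.residue_ids():
            assert contact_number(s, rid, cutoff=10.0) == 0

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        s = random_point_structure(rng, 30, spread=18.0)
        pts = {r.id: representative_point(r) for r in s.residues}
        for rid in s.residue_ids():
            expected = sum(
                1 for other in s.residue_ids() if other != rid
                and np.linalg.norm(pts[other] - pts[rid]) < 10.0)
            assert contact_number(s, rid) == expected


class TestPlanarity:
    def test_coplanar_points_score_zero(self):
        rng = np.random.default_rng(0)
        pts = np.c_[rng.uniform(0, 10, (20, 2)), np.zeros(20)]
        assert plane_rmsd(pts) == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_offsets_give_d(self):
        d = 0.73
        pts = np.array([[0, 0, d], [10, 0, -d], [0, 10, -d], [10, 10, d]])
        assert plane_rmsd(pts) == pytest.approx(d, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_svd_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 15, (20, 3))
        centered = pts - pts.mean(axis=0)
        s_min = np.linalg.svd(centered, compute_uv=False)[-1]
        assert plane_rmsd(pts) == pytest.approx(
            s_min / math.sqrt(len(pts)), abs=1e-9)

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 15, (20, 3))
        rot = Rotation.random(rng=rng).as_matrix()
        moved = pts @ rot.T + np.array([3.0, -8.0, 2.0])
        assert plane_rmsd(moved) == pytest.approx(plane_rmsd(pts), abs=1e-9)

    def test_collinear_degenerates_to_zero(self):
        pts = np.array([[float(i), 0.0, 0.0] for i in range(5)])
        assert plane_rmsd(pts) == 0.0

    def test_on_patch(self, globule_fixture):
        s = globule_fixture.structure
        patches = enumerate_patches(s, globule_fixture.surface)
        pts = np.array([representative_point(s.residue(r))
                        for r in patches[0].members])
        assert planarity_score(s, patches[0]) == pytest.approx(
            plane_rmsd(pts), abs=1e-12)


class TestSecondaryStructure:
    def test_canonical_helix_interior(self, helix_fixture):
        ss = assign_secondary_structure(helix_fixture.structure, "heuristic")
        rids = helix_fixture.structure.residue_ids()
        for rid in rids[1:-1]:
            assert ss[rid] == "helix"
        assert ss[rids[0]] == "coil" and ss[rids[-1]] == "coil"

    def test_short_peptide_all_coil(self):
        fx = fixtures.generate_structure(
            fixtures.FixtureSpec(seed=1, geometry="helix", n_residues=3))
        ss = assign_secondary_structure(fx.structure, "heuristic")
        assert set(ss.values()) == {"coil"}

    def test_extended_strands_assigned(self):
        fx = fixtures.generate_structure(
            fixtures.FixtureSpec(seed=2, geometry="sheet", n_residues=20))
        ss = assign_secondary_structure(fx.structure, "heuristic")
        assert ss == fx.ss_truth
        assert list(ss.values()).count("strand") >= 10

    def test_missing_backbone_is_coil(self):
        s = parse_structure(ONE_ATOM_PDB)
        ss = assign_secondary_structure(s, "heuristic")
        assert ss[ResidueId("A", 1)] == "coil"
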