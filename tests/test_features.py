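"""Attribute correctness against hand-tally oracles, scaling bounds, and
cross-validation hygiene."""

import math

import numpy as np
import pytest

from epitopatch import fixtures
from epitopatch.constants import BLOSUM62_DIAGONAL, PSSM_ALPHABET
from epitopatch.features import (EnergyTable, FeatureScaler,
                                 MappingError, PropensityTable,
                                 ProvenanceError, assemble_patch_features,
                                 burial_bin, conservation_score,
                                 derive_energy_table, derive_propensity_table,
                                 epitope_propensity, featurize_target,
                                 map_pssm_to_chain, parse_pssm, patch_label,
                                 ss_composition, validate_annotation)
from epitopatch.structure import (AccessibilityRecord, ResidueId, SurfacePatch)


def _rec(rid, restype, sidechain, rel=0.5):
    return AccessibilityRecord(rid, restype, sidechain * 2, sidechain, rel, 1.2)


def _rid(i):
    return ResidueId("A", i)


class TestPropensityTable:
    def test_hand_tally_two_targets(self):
        # target 1: epitope {LYS 30 A^2}, rest {LEU 60}; target 2: epitope
        # {LYS 10, LEU 20}, rest {LEU 40, LYS 10}
        t1 = ("t1",
              {_rid(1): _rec(_rid(1), "LYS", 30.0),
               _rid(2): _rec(_rid(2), "LEU", 60.0)},
              [_rid(1), _rid(2)], {_rid(1)})
        t2 = ("t2",
              {_rid(1): _rec(_rid(1), "LYS", 10.0),
               _rid(2): _rec(_rid(2), "LEU", 20.0),
               _rid(3): _rec(_rid(3), "LEU", 40.0),
               _rid(4): _rec(_rid(4), "LYS", 10.0)},
              [_rid(1), _rid(2), _rid(3), _rid(4)], {_rid(1), _rid(2)})
        pc = 1.0
        table = derive_propensity_table([t1, t2], pc)
        # spreadsheet tally: epitope areas LYS=40, LEU=20; rest LYS=10, LEU=100
        total_epi = 40 + 20 + pc * 20
        total_rest = 10 + 100 + pc * 20
        expect_lys = math.log(((40 + pc) / total_epi) / ((10 + pc) / total_rest))
        expect_leu = math.log(((20 + pc) / total_epi) / ((100 + pc) / total_rest))
        assert table["LYS"] == pytest.approx(expect_lys, abs=1e-12)
        assert table["LEU"] == pytest.approx(expect_leu, abs=1e-12)
        assert table.provenance == ("t1", "t2")

    def test_equal_fractions_give_zero(self):
        t = ("t", {_rid(1): _rec(_rid(1), "LYS", 50.0),
                   _rid(2): _rec(_rid(2), "LYS", 50.0)},
             [_rid(1), _rid(2)], {_rid(1)})
        table = derive_propensity_table([t], pseudocount=1.0)
        assert table["LYS"] == pytest.approx(0.0, abs=1e-12)

    def test_absent_type_finite_negative(self):
        t = ("t", {_rid(1): _rec(_rid(1), "LYS", 50.0),
                   _rid(2): _rec(_rid(2), "TRP", 80.0)},
             [_rid(1), _rid(2)], {_rid(1)})
        table = derive_propensity_table([t], pseudocount=1.0)
        assert np.isfinite(table["TRP"]) and table["TRP"] < 0

    def test_permutation_invariant_over_targets(self, small_corpus):
        items = [(t.target_id, t.fixture.records, t.surface, t.epitope)
                 for t in small_corpus]
        a = derive_propensity_table(items)
        b = derive_propensity_table(list(reversed(items)))
        for rt in a.values:
            assert a[rt] == pytest.approx(b[rt], abs=1e-12)


class TestEpitopePropensity:
    table = PropensityTable({"LYS": -0.4, "LEU": 0.0}, {}, {}, 1.0)

    def test_zero_accessibility(self):
        rec = _rec(_rid(1), "LYS", 10.0, rel=0.0)
        assert epitope_propensity("LYS", rec, self.table) == 0.0

    def test_zero_table_value(self):
        rec = _rec(_rid(1), "LEU", 10.0, rel=0.9)
        assert epitope_propensity("LEU", rec, self.table) == 0.0

    def test_product(self):
        rec = _rec(_rid(1), "LYS", 10.0, rel=0.5)
        assert epitope_propensity("LYS", rec, self.table) == \
            pytest.approx(-0.2, abs=1e-12)

    def test_unknown_type_neutral(self):
        rec = _rec(_rid(1), "XXX", 10.0, rel=0.5)
        assert epitope_propensity("XXX", rec, self.table) == 0.0


class TestConservation:
    def test_zero_offsets_round_trip(self):
        seq = "ARNDCQE"
        profile = parse_pssm(fixtures.generate_pssm(seq, [0] * len(seq)))
        for i in range(len(seq)):
            assert conservation_score(profile, i) == 0.0

    def test_planted_offset(self):
        seq = "MKTAYIAK".replace("M", "A")  # standard types only
        profile = parse_pssm(fixtures.generate_pssm(seq, [3] * len(seq)))
        for i in range(len(seq)):
            assert conservation_score(profile, i) == 3.0

    def test_parse_then_hand_subtract(self):
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list(PSSM_ALPHABET), 25))
        offsets = rng.integers(-7, 8, len(seq))
        text = fixtures.generate_pssm(seq, offsets)
        profile = parse_pssm(text)
        # independent parse: raw text line arithmetic
        rows = [ln.split() for ln in text.splitlines()
                if ln.split() and ln.split()[0].isdigit()]
        for i, row in enumerate(rows):
            aa = row[1]
            self_score = int(row[2 + PSSM_ALPHABET.index(aa)])
            assert conservation_score(profile, i) == \
                self_score - BLOSUM62_DIAGONAL[aa]
            assert conservation_score(profile, i) == offsets[i]

    def test_mapping_exact_and_substring(self, helix_fixture):
        s = helix_fixture.structure
        seq = s.sequence("A")
        profile = parse_pssm(fixtures.generate_pssm(seq, [0] * len(seq)))
        mapping = map_pssm_to_chain(profile, s, "A")
        assert len(mapping) == len(seq)
        longer = parse_pssm(fixtures.generate_pssm("AC" + seq, [0] * (len(seq) + 2)))
        mapping2 = map_pssm_to_chain(longer, s, "A")
        assert all(mapping2[rid] == mapping[rid] + 2 for rid in mapping)

    def test_unmappable_profile_is_empty(self, helix_fixture):
        profile = parse_pssm(fixtures.generate_pssm("WWWWYYYY", [0] * 8))
        assert map_pssm_to_chain(profile, helix_fixture.structure, "A") == {}


class TestEnergy:
    def test_uniform_counts_score_zero(self):
        counts = {t: (5.0, 5.0, 5.0, 5.0)
                  for t in ("ALA", "LYS", "LEU", "TRP")}
        table = EnergyTable(counts)
        for rel in (0.0, 0.1, 0.3, 0.9):
            assert table.score("ALA", rel) == pytest.approx(0.0, abs=1e-12)

    def test_always_buried_type_penalised_when_exposed(self):
        counts = {"TRP": (30.0, 0.0, 0.0, 0.0),   # always buried
                  "LYS": (0.0, 10.0, 10.0, 10.0)}
        table = EnergyTable(counts)
        assert table.score("TRP", 0.9) > table.score("TRP", 0.01)

    def test_hand_tallied_log_odds(self):
        counts = {"ALA": (3.0, 1.0, 0.0, 0.0), "LYS": (0.0, 0.0, 2.0, 6.0)}
        pc = 1.0
        table = EnergyTable(counts, pc)
        # residue ALA at rel_acc 0.6 -> bin 3
        p_b_t = (0.0 + pc) / (4.0 + 4 * pc)
        p_b = (6.0 + 2 * pc) / (12.0 + 8 * pc)
        assert table.score("ALA", 0.6) == \
            pytest.approx(-math.log(p_b_t / p_b), abs=1e-12)

    def test_bins(self):
        assert [burial_bin(v) for v in (0.0, 0.049, 0.05, 0.24, 0.25, 0.49,
                                        0.5, 1.2)] == [0, 0, 1, 1, 2, 2, 3, 3]

    def test_derived_from_corpus_counts(self, small_corpus):
        t = small_corpus[0]
        table = derive_energy_table([(t.target_id, t.fixture.records)])
        hand = {}
        for rec in t.fixture.records.values():
            hand.setdefault(rec.restype, [0.0] * 4)[burial_bin(rec.rel_acc)] += 1
        for rt, row in hand.items():
            assert list(table.counts[rt]) == row


class TestPatchLevel:
    def _patch(self, ids, size=20):
        return SurfacePatch(ids[0], tuple(ids), size)

    def test_ss_composition_fractions(self):
        ids = [_rid(i) for i in range(20)]
        patch = self._patch(ids)
        all_coil = {r: "coil" for r in ids}
        all_helix = {r: "helix" for r in ids}
        mixed = {r: ("coil" if i < 5 else "strand")
                 for i, r in enumerate(ids)}
        assert ss_composition(patch, all_coil) == 1.0
        assert ss_composition(patch, all_helix) == 0.0
        assert ss_composition(patch, mixed) == 0.25

    def test_patch_label_scaling(self):
        ids = [_rid(i) for i in range(20)]
        patch = self._patch(ids)
        assert patch_label(patch, set()) == 0.0
        assert patch_label(patch, set(ids)) == 1.0
        assert patch_label(patch, set(ids[:5])) == 0.25

    def test_annotation_validation(self, helix_fixture):
        with pytest.raises(MappingError):
            validate_annotation({ResidueId("Q", 999)},
                                helix_fixture.structure)

    def test_constant_member_scores_average_to_constant(self):
        ids = [_rid(i) for i in range(10)]
        patch = self._patch(ids, size=10)
        scores = {r: (0.3, -1.0, 2.5) for r in ids}
        fv = assemble_patch_features(patch, scores, contact=7, planarity=1.1,
                                     ss_frac=0.4)
        assert fv.raw[:3] == pytest.approx([0.3, -1.0, 2.5])
        assert fv.raw[3:] == pytest.approx([7, 1.1, 0.4])

    def test_averages_match_direct_mean_and_are_bounded(self):
        rng = np.random.default_rng(2)
        ids = [_rid(i) for i in range(15)]
        patch = self._patch(ids, size=15)
        scores = {r: tuple(rng.normal(size=3)) for r in ids}
        fv = assemble_patch_features(patch, scores, 1, 1, 1)
        arr = np.array([scores[r] for r in patch.members])
        assert fv.raw[:3] == pytest.approx(arr.mean(axis=0), abs=1e-12)
        assert np.all(fv.raw[:3] >= arr.min(axis=0) - 1e-12)
        assert np.all(fv.raw[:3] <= arr.max(axis=0) + 1e-12)


class TestScaler:
    def test_endpoints_and_clamping(self):
        raw = np.array([[0.0, 10.0], [5.0, 20.0], [10.0, 30.0]])
        sc = FeatureScaler().fit(raw)
        assert sc.transform([0.0, 10.0])[0] == pytest.approx([0.0, 0.0])
        assert sc.transform([10.0, 30.0])[0] == pytest.approx([1.0, 1.0])
        assert sc.transform([-5.0, 40.0])[0] == pytest.approx([0.0, 1.0])

    def test_inverse_identity_in_range(self):
        rng = np.random.default_rng(0)
        raw = rng.uniform(-3, 7, (40, 6))
        sc = FeatureScaler().fit(raw)
        back = sc.inverse(sc.transform(raw))
        assert back == pytest.approx(raw, abs=1e-9)

    def test_constant_attribute_maps_to_half(self):
        raw = np.array([[1.0, 4.0], [1.0, 5.0]])
        sc = FeatureScaler().fit(raw)
        assert sc.transform([1.0, 4.5])[0][0] == 0.5

    def test_unfitted_raises(self):
        with pytest.raises(RuntimeError):
            FeatureScaler().transform([1.0])


class TestFeaturizeTarget:
    def test_scaled_features_in_unit_cube(self, small_prepared):
        from epitopatch.svr import derive_tables, _featurize
        prop, energy = derive_tables(small_prepared)
        raws = [_featurize(t, prop, energy, 10.0, "sidechain_center",
                           True, allow_self=True)
                for t in small_prepared]
        raw = np.vstack([f.raw_features for f in raws])
        sc = FeatureScaler().fit(raw)
        scaled = sc.transform(raw)
        assert scaled.min() >= 0.0 and scaled.max() <= 1.0
        labels = np.concatenate([f.labels for f in raws])
        assert labels.min() >= 0.0 and labels.max() <= 1.0

    def test_loo_hygiene_enforced(self, small_prepared):
        from epitopatch.svr import derive_tables
        prop, energy = derive_tables(small_prepared)
        t = small_prepared[0]
        with pytest.raises(ProvenanceError):
            featurize_target(t.target_id, t.structure, t.records, t.surface,
                             t.patches, t.ss, prop, energy)
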