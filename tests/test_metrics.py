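"""Structure and sequence metrics: exact values, invariances, oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import apply_rigid, ca_only_structure, random_rigid_motion
from foldcritic.metrics import (
    gdt_ts,
    kabsch_superpose,
    lddt,
    sequence_recovery,
    spearman,
    tm_d0,
    tm_score,
)
from foldcritic.synthetic import perturb_structure
from oracles import lddt_bruteforce, quaternion_rmsd, spearman_bruteforce


class TestKabsch:
    def test_identical_points_give_identity_transform(self):
        pts = np.random.default_rng(0).normal(size=(8, 3))
        sup = kabsch_superpose(pts, pts)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(sup.translation, 0.0, atol=1e-12)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)

    def test_recovers_known_rigid_motion(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 3))
        rot90 = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        moved = pts @ rot90.T + np.array([5.0, 0.0, 0.0])
        sup = kabsch_superpose(moved, pts)
        assert sup.rmsd <= 1e-9
        np.testing.assert_allclose(sup.rotation @ rot90, np.eye(3), atol=1e-9)

    def test_rotation_is_always_proper(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.normal(size=(5, 3))
            b = rng.normal(size=(5, 3))
            sup = kabsch_superpose(a, b)
            assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_matches_quaternion_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(3, 40))
            a = rng.normal(scale=5.0, size=(n, 3))
            b = rng.normal(scale=5.0, size=(n, 3))
            assert kabsch_superpose(a, b).rmsd == pytest.approx(
                quaternion_rmsd(a, b), abs=1e-9)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))


class TestTmScore:
    def test_self_comparison_is_exactly_one(self, hairpin40):
        assert tm_score(hairpin40, hairpin40) == 1.0

    def test_rigid_motion_invariance(self, hairpin40):
        rng = np.random.default_rng(7)
        decoy = perturb_structure(hairpin40, 1.0, seed=5)
        base = tm_score(decoy, hairpin40)
        for _ in range(3):
            rot, trans = random_rigid_motion(rng)
            moved = apply_rigid(decoy, rot, trans)
            assert tm_score(moved, hairpin40) == pytest.approx(base, abs=1e-6)

    def test_d0_floor_for_short_chains(self):
        assert tm_d0(8) == 0.5
        assert tm_d0(15) == 0.5
        assert tm_d0(100) == pytest.approx(1.24 * 85 ** (1 / 3) - 1.8)

    def test_normalization_asymmetry_counterexample(self):
        """TM(a,b | L_b) and TM(b,a | L_a) differ when lengths differ."""
        rng = np.random.default_rng(11)
        ca_long = np.cumsum(rng.normal(scale=2.0, size=(30, 3)), axis=0)
        a = ca_only_structure(ca_long[:20] + rng.normal(scale=1.0, size=(20, 3)))
        b = ca_only_structure(ca_long[:30])
        ab = tm_score(a, b)           # normalized by len(b) = 30
        ba = tm_score(b, a)           # normalized by len(a) = 20
        assert abs(ab - ba) > 0.01

    def test_too_few_common_ca_rejected(self):
        a = ca_only_structure(np.zeros((2, 3)))
        b = ca_only_structure(np.ones((2, 3)))
        with pytest.raises(ValueError):
            tm_score(a, b)


class TestGdtTs:
    def test_identical_structures_score_one(self, hairpin40):
        assert gdt_ts(hairpin40, hairpin40) == 1.0

    def test_fixed_frame_hand_count(self):
        """Residues displaced by {0.5, 1.5, 3.0, 9.0} Å give
        (1 + 2 + 3 + 3) / 16 = 0.5625 with no superposition search."""
        ref_ca = np.array([[0, 0, 0], [4, 0, 0], [8, 0, 0], [12, 0, 0]], float)
        shifts = np.array([0.5, 1.5, 3.0, 9.0])
        mod_ca = ref_ca + np.array([[0, 0, s] for s in shifts])
        score = gdt_ts(ca_only_structure(mod_ca), ca_only_structure(ref_ca),
                       superpose=False)
        assert score == pytest.approx(0.5625)

    def test_search_dominates_fixed_frame(self, hairpin40):
        rng = np.random.default_rng(13)
        for seed in range(5):
            decoy = perturb_structure(hairpin40, rng.uniform(0.5, 3.0), seed=seed)
            rot, trans = random_rigid_motion(rng)
            decoy = apply_rigid(decoy, rot, trans)
            assert gdt_ts(decoy, hairpin40) >= gdt_ts(decoy, hairpin40,
                                                      superpose=False)

    def test_search_mode_rigid_invariance(self, hairpin40):
        rng = np.random.default_rng(17)
        decoy = perturb_structure(hairpin40, 1.0, seed=2)
        base = gdt_ts(decoy, hairpin40)
        rot, trans = random_rigid_motion(rng)
        assert gdt_ts(apply_rigid(decoy, rot, trans), hairpin40) == pytest.approx(
            base, abs=1e-6)


class TestLddt:
    def test_identical_structures_score_one(self, hairpin40):
        total, per_res = lddt(hairpin40, hairpin40)
        assert total == 1.0
        assert np.nanmin(per_res) == 1.0

    def test_single_changed_pair_hand_value(self):
        """One included pair moved by 1.5 Å contributes (0+0+1+1)/4 = 0.5."""
        ref_ca = np.array([[0, 0, 0], [4, 0, 0], [8, 0, 0]], float)
        mod_ca = ref_ca.copy()
        mod_ca[2, 0] += 1.5      # only the (0, 2) pair distance changes
        ref = ca_only_structure(ref_ca)
        mod = ca_only_structure(mod_ca)
        total, per_res = lddt(mod, ref)
        # residue 1 has no |i-j| >= 2 partner within range except none
        oracle_total, oracle_per = lddt_bruteforce(mod_ca, ref_ca, np.arange(3))
        assert total == pytest.approx(oracle_total)
        assert per_res[0] == pytest.approx(0.5)
        assert per_res[2] == pytest.approx(0.5)

    def test_matches_bruteforce_on_random_pairs(self, hairpin40):
        for seed in range(5):
            decoy = perturb_structure(hairpin40, 1.5, seed=seed)
            total, per_res = lddt(decoy, hairpin40)
            o_total, o_per = lddt_bruteforce(decoy.ca, hairpin40.ca,
                                             np.arange(len(hairpin40)))
            assert total == pytest.approx(o_total, abs=1e-12)
            np.testing.assert_allclose(per_res, o_per, atol=1e-12)

    def test_superposition_free(self, hairpin40):
        rng = np.random.default_rng(23)
        decoy = perturb_structure(hairpin40, 1.0, seed=9)
        base, _ = lddt(decoy, hairpin40)
        rot, trans = random_rigid_motion(rng)
        moved, _ = lddt(apply_rigid(decoy, rot, trans), hairpin40)
        assert moved == pytest.approx(base, abs=1e-9)


class TestSequenceRecovery:
    @pytest.mark.parametrize("designed,native,expected", [
        ("ACDEF", "ACDEF", 1.0),
        ("ACDEF", "ACDFF", 0.8),
        ("AAAA", "CCCC", 0.0),
    ])
    def test_exact_values(self, designed, native, expected):
        assert sequence_recovery(designed, native) == pytest.approx(expected)

    def test_random_sequences_recover_at_chance_level(self):
        """Two random 20-letter sequences match ~5% of positions."""
        rng = np.random.default_rng(29)
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        vals = []
        for _ in range(100):
            a = "".join(rng.choice(letters, 1000))
            b = "".join(rng.choice(letters, 1000))
            vals.append(sequence_recovery(a, b))
        se = np.sqrt(0.05 * 0.95 / 1000) / np.sqrt(100)
        assert np.mean(vals) == pytest.approx(0.05, abs=3 * se)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sequence_recovery("AC", "ACD")


class TestSpearman:
    def test_monotone_relationships(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert spearman(x, [2.0, 4.0, 9.0, 100.0]) == pytest.approx(1.0)
        assert spearman(x, [5.0, 3.0, 2.0, 1.0]) == pytest.approx(-1.0)

    def test_tie_handling_matches_bruteforce(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
        y = [3.0, 1.0, 4.0, 4.0, 5.0, 9.0]
        assert spearman(x, y) == pytest.approx(spearman_bruteforce(x, y),
                                               abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=20))
    def test_agrees_with_bruteforce_on_random_lists(self, xs):
        rng = np.random.default_rng(abs(hash(tuple(xs))) % 2**31)
        ys = list(rng.normal(size=len(xs)))
        if len(set(xs)) < 2:
            return
        assert spearman(xs, ys) == pytest.approx(spearman_bruteforce(xs, ys),
                                                 abs=1e-12)
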