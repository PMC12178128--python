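"""Template featurization: virtual Cβ, masking, torsions, gap encoding."""

import numpy as np
import pytest

from conftest import apply_rigid, random_rigid_motion
from foldcritic.structure_io import ATOM_INDEX
from foldcritic.synthetic import build_backbone
from foldcritic.template_features import (
    GAP_INDEX,
    GeometryError,
    TemplateFeatures,
    decode_onehot,
    featurize_template,
    gap_sequence,
    mask_to_backbone,
    virtual_cbeta,
)


class TestVirtualCbeta:
    def test_ideal_bond_length_and_angle(self, helix20):
        i = 5
        n, ca, c = (helix20.coords[i, ATOM_INDEX[a]] for a in ("N", "CA", "C"))
        cb = virtual_cbeta(n, ca, c)
        assert np.linalg.norm(cb - ca) == pytest.approx(1.522, abs=1e-6)
        v1 = (n - ca) / np.linalg.norm(n - ca)
        v2 = (cb - ca) / np.linalg.norm(cb - ca)
        angle = np.degrees(np.arccos(np.dot(v1, v2)))
        assert angle == pytest.approx(110.4, abs=1e-4)

    def test_l_chirality_sign_is_consistent(self, hairpin40):
        signs = set()
        for i in range(len(hairpin40)):
            n, ca, c = (hairpin40.coords[i, ATOM_INDEX[a]] for a in ("N", "CA", "C"))
            cb = virtual_cbeta(n, ca, c)
            vol = np.dot(np.cross(ca - n, c - n), cb - n)
            signs.add(np.sign(vol))
        # one consistent handedness across all residues
        assert signs == {-1.0}

    def test_rigid_equivariance(self, helix20):
        rng = np.random.default_rng(31)
        rot, trans = random_rigid_motion(rng)
        i = 7
        n, ca, c = (helix20.coords[i, ATOM_INDEX[a]] for a in ("N", "CA", "C"))
        moved = virtual_cbeta(n @ rot.T + trans, ca @ rot.T + trans, c @ rot.T + trans)
        expected = virtual_cbeta(n, ca, c) @ rot.T + trans
        np.testing.assert_allclose(moved, expected, atol=1e-9)

    def test_degenerate_frame_rejected(self):
        with pytest.raises(GeometryError):
            virtual_cbeta(np.zeros(3), np.zeros(3), np.ones(3))
        with pytest.raises(GeometryError):
            # collinear
            virtual_cbeta(np.array([0.0, 0, 0]), np.array([1.0, 0, 0]),
                          np.array([2.0, 0, 0]))


class TestMaskToBackbone:
    def test_every_glycine_gains_a_cbeta(self, three_res_pdb):
        from foldcritic.structure_io import read_pdb

        st = read_pdb(three_res_pdb)
        assert not st.atom_present("CB")[1]     # glycine
        out = mask_to_backbone(st)
        assert out.atom_present("CB").all()

    def test_missing_n_leaves_cb_absent(self, helix20):
        st = helix20.copy()
        st.atom_mask[4, ATOM_INDEX["N"]] = False
        st.atom_mask[4, ATOM_INDEX["CB"]] = False
        st.coords[4, ATOM_INDEX["CB"]] = np.nan
        out = mask_to_backbone(st)
        assert not out.atom_present("CB")[4]

    def test_existing_cb_is_never_overwritten(self, helix20):
        st = helix20.copy()
        shifted = st.coords[3, ATOM_INDEX["CB"]] + np.array([0.3, 0.0, 0.0])
        st.coords[3, ATOM_INDEX["CB"]] = shifted
        out = mask_to_backbone(st)
        np.testing.assert_allclose(out.coords[3, ATOM_INDEX["CB"]], shifted)


class TestGapSequence:
    def test_rows_are_one_hot_at_gap(self):
        enc = gap_sequence(5)
        assert enc.shape == (5, 22)
        np.testing.assert_array_equal(enc.sum(axis=1), np.ones(5))
        assert (np.argmax(enc, axis=1) == GAP_INDEX).all()
        assert np.count_nonzero(enc) == 5

    def test_decoding_round_trip(self):
        assert decode_onehot(gap_sequence(4)) == "----"

    def test_rejects_nonpositive_length(self):
        with pytest.raises(ValueError):
            gap_sequence(0)


class TestFeaturizeTemplate:
    def test_distance_matrix_symmetric_zero_diagonal(self, helix20):
        feats = featurize_template(mask_to_backbone(helix20))
        feats.validate()
        d = feats.cbeta_distance_matrix
        np.testing.assert_allclose(d, d.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(d), 0.0, atol=1e-12)

    def test_terminus_torsion_masking(self, helix20):
        feats = featurize_template(mask_to_backbone(helix20))
        assert not feats.torsion_mask[0, 0]          # phi undefined at N-term
        assert not feats.torsion_mask[0, 2]          # omega undefined at N-term
        assert not feats.torsion_mask[-1, 1]         # psi undefined at C-term
        assert feats.torsion_mask[1:, 0].all()
        assert feats.torsion_mask[:-1, 1].all()
        assert feats.torsion_mask[1:, 2].all()

    def test_gap_mode_matches_gap_sequence(self, helix20):
        feats = featurize_template(mask_to_backbone(helix20))
        np.testing.assert_array_equal(feats.aatype_onehot,
                                      gap_sequence(len(helix20)))

    def test_helix_torsions_round_trip(self):
        """A backbone built at φ=−57°, ψ=−47° measures back those angles."""
        st = build_backbone(np.full(10, -57.0), np.full(10, -47.0),
                            np.full(10, 180.0), "A" * 10)
        feats = featurize_template(st)
        torsions = np.arctan2(feats.torsions[..., 0], feats.torsions[..., 1])
        np.testing.assert_allclose(np.degrees(torsions[1:, 0]), -57.0, atol=0.06)
        np.testing.assert_allclose(np.degrees(torsions[:-1, 1]), -47.0, atol=0.06)
        np.testing.assert_allclose(np.abs(np.degrees(torsions[1:, 2])), 180.0,
                                   atol=0.06)

    def test_rigid_motion_invariance(self, hairpin40):
        rng = np.random.default_rng(37)
        base = featurize_template(mask_to_backbone(hairpin40))
        rot, trans = random_rigid_motion(rng)
        moved = featurize_template(mask_to_backbone(apply_rigid(hairpin40, rot, trans)))
        np.testing.assert_allclose(moved.cbeta_distance_matrix,
                                   base.cbeta_distance_matrix, atol=1e-6)
        np.testing.assert_allclose(moved.torsions[base.torsion_mask],
                                   base.torsions[base.torsion_mask], atol=1e-6)

    def test_gap_features_blind_to_sequence_identity(self, helix20):
        """Permuting sequence letters changes nothing in gap mode."""
        st = mask_to_backbone(helix20)
        shuffled = st.copy()
        shuffled.sequence = st.sequence[::-1]
        a = featurize_template(st, sequence_mode="gap")
        b = featurize_template(shuffled, sequence_mode="gap")
        np.testing.assert_array_equal(a.aatype_onehot, b.aatype_onehot)
        np.testing.assert_allclose(a.cbeta_distance_matrix,
                                   b.cbeta_distance_matrix)

    def test_native_mode_differs_only_in_aatype(self, helix20):
        st = mask_to_backbone(helix20)
        gap = featurize_template(st, sequence_mode="gap")
        nat = featurize_template(st, sequence_mode="native")
        assert not np.array_equal(gap.aatype_onehot, nat.aatype_onehot)
        assert decode_onehot(nat.aatype_onehot) == st.sequence
        np.testing.assert_allclose(gap.cbeta_distance_matrix,
                                   nat.cbeta_distance_matrix)
        np.testing.assert_allclose(gap.torsions, nat.torsions)

    def test_save_load_round_trip(self, helix20, tmp_path):
        feats = featurize_template(mask_to_backbone(helix20))
        feats.save(tmp_path / "feats")
        loaded = TemplateFeatures.load(tmp_path / "feats")
        for name in TemplateFeatures._FIELDS:
            np.testing.assert_array_equal(getattr(feats, name),
                                          getattr(loaded, name))
        assert loaded.source_structure is None

    def test_too_few_usable_residues_rejected(self, helix20):
        st = helix20.subset(np.arange(2))
        st.atom_mask[:, ATOM_INDEX["CB"]] = False
        st.atom_mask[:, ATOM_INDEX["N"]] = False
        with pytest.raises(ValueError):
            featurize_template(st)
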