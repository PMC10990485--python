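"""Ideal-observer strategy models: rosters, mappings, predictions, accuracy."""

import numpy as np
import pytest

from rotgen.models import (
    PredictionContext,
    derive_ideal_mapping,
    get_model,
    model_roster,
    predict,
    training_accuracy,
)
from rotgen.task import (
    ROTATIONS,
    QuadrupletTrial,
    Transformation,
    enumerate_quadruplets,
    pattern_of,
    realise_quadruplet,
)


class TestRoster:
    def test_roster_sizes(self):
        near = model_roster("near")
        far = model_roster("far")
        assert [m.name for m in near] == [
            "R", "Rp", "1Di_u", "1Dj_u", "1Di_s", "1Dj_s", "2D"]
        assert len(far) == 11
        assert "1Dij_u" in {m.name for m in far}

    def test_parameter_counts(self):
        for m in model_roster("far"):
            assert m.n_params == (0 if m.name == "R" else 1)

    def test_cross_mapped_models_swap_the_far_dimension(self):
        assert get_model("1Dij_u").far_dimension == "j"
        assert get_model("1Dji_s").far_dimension == "i"
        assert get_model("1Di_u").far_dimension == "i"


class TestIdealMappings:
    def test_canonical_only_mappings_are_diagnostic(self, ctx_canonical):
        mapping = derive_ideal_mapping(get_model("1Di_u"), ctx_canonical)
        assert np.allclose(mapping["ABBA"], [1, 0, 0])
        assert np.allclose(mapping["ABAB"], [0, 1, 0])
        assert np.allclose(mapping["AABB"], [0, 0, 1])

    def test_mixed_rotations_make_unsigned_patterns_ambiguous(self, ctx_mixed):
        mapping = derive_ideal_mapping(get_model("1Di_u"), ctx_mixed)
        assert np.allclose(mapping["ABBA"], [0.5, 0.5, 0.0])

    def test_signed_i_patterns_stay_unique_under_mixed_training(self, ctx_mixed):
        mapping = derive_ideal_mapping(get_model("1Di_s"), ctx_mixed)
        assert len(mapping) == 6
        for vec in mapping.values():
            assert sorted(vec) == [0.0, 0.0, 1.0]

    def test_mapping_requires_a_1d_model(self, ctx_canonical):
        with pytest.raises(ValueError):
            derive_ideal_mapping(get_model("2D"), ctx_canonical)


class TestPredict:
    def test_random_model_is_uniform(self, ctx_canonical):
        trial = realise_quadruplet(2, Transformation(180), (1, 1))
        assert np.allclose(predict(get_model("R"), ctx_canonical, trial), 1 / 3)

    def test_2d_matches_rotated_templates(self, ctx_canonical):
        trial = realise_quadruplet(1, Transformation(180), (0, 1),
                                   phase="near_transfer", feedback=False)
        assert np.allclose(predict(get_model("2D"), ctx_canonical, trial),
                           [0, 1, 0])

    def test_1d_unsigned_identifies_canonical_category(self, ctx_canonical):
        trial = realise_quadruplet(2, Transformation(0), (1, 0))
        assert np.allclose(predict(get_model("1Di_u"), ctx_canonical, trial),
                           [0, 0, 1])

    def test_nongeneraliser_tracks_phase(self, ctx_canonical):
        rp = get_model("Rp")
        train = realise_quadruplet(1, Transformation(0), (0, 0),
                                   phase="training")
        transfer = realise_quadruplet(1, Transformation(90), (0, 0),
                                      phase="near_transfer", feedback=False)
        assert np.allclose(predict(rp, ctx_canonical, train), [0, 1, 0])
        assert np.allclose(predict(rp, ctx_canonical, transfer), 1 / 3)

    def test_corrupt_quadruplet_rejected_by_2d(self, ctx_canonical):
        bad = QuadrupletTrial(
            0, Transformation(0), (0, 0),
            ((0, 0), (2, 0), (2, 1), (0, 1)))
        with pytest.raises(ValueError):
            predict(get_model("2D"), ctx_canonical, bad)

    def test_all_predictions_are_distributions(self, ctx_mixed):
        trials = [
            t for far in (False, True)
            for t in enumerate_quadruplets(
                ROTATIONS, far_transfer=far,
                phase="far_transfer" if far else "near_transfer")
        ]
        for model in model_roster("far"):
            for trial in trials:
                p = predict(model, ctx_mixed, trial)
                assert p.min() >= 0
                assert abs(p.sum() - 1) < 1e-12

    def test_2d_is_rotation_invariant(self, ctx_canonical):
        model = get_model("2D")
        for cat in range(3):
            for anchor in ((0, 0), (2, 1)):
                preds = [
                    predict(model, ctx_canonical,
                            realise_quadruplet(cat, Transformation(rot), anchor))
                    for rot in ROTATIONS
                ]
                for p in preds[1:]:
                    assert np.allclose(p, preds[0])

    def test_far_cross_mapping_reads_the_swapped_dimension(self, ctx_mixed):
        """1Dij reads the far manifold's j axis as if it were i."""
        cross = get_model("1Dij_u")
        plain = get_model("1Di_u")
        for cat in range(3):
            far = realise_quadruplet(cat, Transformation(90, True), (1, 1),
                                     phase="far_transfer", feedback=False)
            # a trial with i/j coordinates swapped, on the original manifold
            swapped = QuadrupletTrial(
                far.category, Transformation(90),
                (far.anchor[1], far.anchor[0]),
                tuple((j, i) for i, j in far.positions),
                phase="near_transfer", feedback=False)
            assert np.allclose(predict(cross, ctx_mixed, far),
                               predict(plain, ctx_mixed, swapped))


class TestTrainingAccuracy:
    def test_accuracy_table_matches_the_design(self, ctx_canonical, ctx_mixed):
        expected_canonical = {"R": 1 / 3, "Rp": 1.0, "1Di_u": 1.0, "1Dj_u": 1.0,
                              "1Di_s": 1.0, "1Dj_s": 1.0, "2D": 1.0}
        expected_mixed = {"R": 1 / 3, "Rp": 1.0, "1Di_u": 0.5, "1Dj_u": 0.5,
                          "1Di_s": 1.0, "1Dj_s": 0.5, "2D": 1.0}
        for name, acc in expected_canonical.items():
            assert training_accuracy(get_model(name), ctx_canonical) == pytest.approx(acc)
        for name, acc in expected_mixed.items():
            assert training_accuracy(get_model(name), ctx_mixed) == pytest.approx(acc)

    def test_1d_models_misassign_90_degree_rotations(self, ctx_canonical):
        """Against an oracle built directly from pattern counts.

        For canonical-only training, every 90-degree trial's modal category
        under a 1D model must differ from the true category (this is what
        makes the transfer phase diagnostic of strategy).
        """
        # oracle: pattern -> training category counts, recomputed from scratch
        for name in ("1Di_u", "1Dj_u"):
            model = get_model(name)
            oracle: dict[str, np.ndarray] = {}
            for t in enumerate_quadruplets((0,)):
                tok = pattern_of(t, model.tracked_dimension, signed=model.signed)
                oracle.setdefault(tok, np.zeros(3))[t.category] += 1
            for t in enumerate_quadruplets((90,), phase="near_transfer"):
                tok = pattern_of(t, model.tracked_dimension, signed=model.signed)
                oracle_modal = int(np.argmax(oracle[tok]))
                p = predict(model, ctx_canonical, t)
                assert int(np.argmax(p)) == oracle_modal
                assert oracle_modal != t.category
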