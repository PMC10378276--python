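"""Pixel-forest training, vote-fraction probabilities and evaluation."""

from __future__ import annotations

import numpy as np
import pytest

from naevoscreen.classifier import (
    ForestConfig,
    MissingClassError,
    PixelForestClassifier,
    ProbabilityMap,
    evaluate,
    load_probability_map,
    predict_probability,
    save_probability_map,
    train_frf,
)
from naevoscreen.image_io import LABEL_ANOMALOUS, LABEL_REGULAR

from conftest import random_feature_stack


def _fit_small_forest(n_trees=7, seed=0, shape=(16, 16), n_features=5):
    """Forest on a noise stack with a block-labeled mask."""
    stack = random_feature_stack(*shape, n_features, seed)
    # make the two classes actually separable on feature 0
    stack.values[: shape[0] // 2, :, 0] += 4.0
    mask = np.zeros(shape, dtype=np.uint8)
    mask[: shape[0] // 2, ::2] = LABEL_ANOMALOUS
    mask[shape[0] // 2 :, ::2] = LABEL_REGULAR
    model = train_frf(stack, mask, ForestConfig(n_trees=n_trees, seed=seed))
    return model, stack, mask


class TestTraining:
    def test_two_separable_pixels_are_interpolated(self):
        stack = random_feature_stack(2, 1, 3, 0)
        stack.values[0, 0] = [5.0, 0, 0]
        stack.values[1, 0] = [-5.0, 0, 0]
        mask = np.array([[LABEL_ANOMALOUS], [LABEL_REGULAR]], dtype=np.uint8)
        model = train_frf(stack, mask, ForestConfig(n_trees=10, seed=1))
        prob = predict_probability(model, stack)
        assert prob.p_c2[0, 0] > 0.5
        assert prob.p_c2[1, 0] < 0.5

    def test_training_is_deterministic_for_fixed_seed(self):
        a, stack, _ = _fit_small_forest(seed=4)
        b, _, _ = _fit_small_forest(seed=4)
        np.testing.assert_array_equal(
            a.vote_fractions(stack.as_matrix()),
            b.vote_fractions(stack.as_matrix()),
        )

    def test_missing_class_raises(self):
        stack = random_feature_stack(4, 4, 3, 0)
        mask = np.zeros((4, 4), dtype=np.uint8)
        mask[0, 0] = LABEL_REGULAR
        with pytest.raises(MissingClassError):
            train_frf(stack, mask)

    def test_dimension_mismatch_raises(self):
        stack = random_feature_stack(4, 4, 3, 0)
        with pytest.raises(ValueError):
            train_frf(stack, np.zeros((5, 5), dtype=np.uint8))

    def test_training_pixel_accuracy_on_synthetic_fixture(
        self, trained_model, small_stack, sparse_mask
    ):
        """Forests interpolate their training set nearly noiselessly."""
        labeled = sparse_mask.ravel() != 0
        X = small_stack.as_matrix()[labeled]
        y = sparse_mask.ravel()[labeled]
        pred = trained_model.predict(X)
        assert (pred == y).mean() >= 0.95

    def test_mask_construction_order_does_not_change_predictions(self):
        """Labels written into the mask in scrambled order give the same
        mask, hence identical fits: ordering is structural, not caller-set."""
        _, stack, mask = _fit_small_forest(seed=2)
        coords = np.argwhere(mask != 0)
        rng = np.random.default_rng(0)
        scrambled = np.zeros_like(mask)
        for r, c in coords[rng.permutation(len(coords))]:
            scrambled[r, c] = mask[r, c]
        a = train_frf(stack, mask, ForestConfig(n_trees=7, seed=3))
        b = train_frf(stack, scrambled, ForestConfig(n_trees=7, seed=3))
        np.testing.assert_array_equal(
            a.vote_fractions(stack.as_matrix()),
            b.vote_fractions(stack.as_matrix()),
        )


class TestProbabilityMap:
    def test_vote_fraction_matches_per_tree_oracle(self):
        """p_c2 must equal exhaustive per-estimator vote counting."""
        model, stack, _ = _fit_small_forest(n_trees=7, seed=5)
        prob = predict_probability(model, stack)
        forest = model._sklearn_forest_
        X = stack.as_matrix()
        votes = np.zeros(X.shape[0])
        for est in forest.estimators_:
            # per-estimator predictions are encoded class indices
            votes += forest.classes_[est.predict(X).astype(int)] == LABEL_ANOMALOUS
        expected = (votes / 7).reshape(16, 16)
        np.testing.assert_array_equal(prob.p_c2, expected)

    def test_probabilities_normalize_everywhere(self):
        model, stack, _ = _fit_small_forest(n_trees=9, seed=6)
        prob = predict_probability(model, stack)
        np.testing.assert_allclose(prob.p_c1 + prob.p_c2, 1.0, atol=1e-12)
        assert prob.p_c2.min() >= 0 and prob.p_c2.max() <= 1

    def test_vote_fractions_are_multiples_of_tree_count(self):
        model, stack, _ = _fit_small_forest(n_trees=5, seed=7)
        prob = predict_probability(model, stack)
        np.testing.assert_allclose(
            np.round(prob.p_c2 * 5), prob.p_c2 * 5, atol=1e-12
        )

    def test_channel_mismatch_rejected(self):
        model, _, _ = _fit_small_forest()
        other = random_feature_stack(16, 16, 4, 0)
        with pytest.raises(ValueError):
            predict_probability(model, other)

    def test_monotone_threshold_subsets(self):
        model, stack, _ = _fit_small_forest(n_trees=9, seed=8)
        prob = predict_probability(model, stack)
        low = prob.p_c2 > 0.3
        high = prob.p_c2 > 0.7
        assert np.all(low | ~high)  # high-threshold set subset of low's

    def test_inconsistent_map_rejected(self):
        with pytest.raises(ValueError):
            ProbabilityMap(p_c1=np.zeros((2, 2)), p_c2=np.zeros((2, 2)))


class TestPersistence:
    def test_json_round_trip_preserves_predictions(self, tmp_path):
        model, stack, _ = _fit_small_forest(n_trees=7, seed=9)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = PixelForestClassifier.load(path)
        np.testing.assert_array_equal(
            model.vote_fractions(stack.as_matrix()),
            loaded.vote_fractions(stack.as_matrix()),
        )
        assert loaded.channel_names_ == model.channel_names_

    def test_wrong_format_rejected(self, tmp_path):
        path = tmp_path / "junk.json"
        path.write_text('{"format": "something-else"}')
        with pytest.raises(ValueError):
            PixelForestClassifier.load(path)

    def test_probability_map_tiff_round_trip(self, tmp_path):
        rng = np.random.default_rng(10)
        p_c2 = np.round(rng.random((12, 9)) * 8) / 8
        prob = ProbabilityMap(p_c1=1 - p_c2, p_c2=p_c2)
        path = tmp_path / "prob.tiff"
        save_probability_map(path, prob)
        loaded = load_probability_map(path)
        np.testing.assert_allclose(loaded.p_c2, p_c2, atol=1e-7)


class TestEvaluate:
    @staticmethod
    def _map_from(pred_pos: np.ndarray) -> ProbabilityMap:
        p_c2 = np.where(pred_pos, 1.0, 0.0)
        return ProbabilityMap(p_c1=1 - p_c2, p_c2=p_c2)

    def test_formula_instantiation(self):
        truth = np.full((1, 10), LABEL_ANOMALOUS, dtype=np.uint8)
        truth[0, 8:] = LABEL_REGULAR
        pred = np.zeros((1, 10), dtype=bool)
        pred[0, :8] = True   # 8 TP on the anomalous pixels
        pred[0, 8:] = True   # 2 FP on the regular pixels
        report = evaluate(self._map_from(pred), truth, 0.5)
        assert (report.tp, report.fp, report.fn) == (8, 2, 0)
        assert report.precision == pytest.approx(0.8)
        assert report.recall == pytest.approx(1.0)

    def test_perfect_prediction(self):
        truth = np.array([[1, 2], [2, 1]], dtype=np.uint8)
        report = evaluate(self._map_from(truth == 2), truth, 0.5)
        assert report.precision == 1.0 and report.recall == 1.0

    def test_complement_prediction_scores_zero(self):
        truth = np.array([[1, 2], [2, 1]], dtype=np.uint8)
        report = evaluate(self._map_from(truth == 1), truth, 0.5)
        assert report.precision == 0.0 and report.recall == 0.0

    def test_undefined_precision_flagged_not_zeroed(self):
        truth = np.array([[1, 2]], dtype=np.uint8)
        report = evaluate(self._map_from(np.zeros((1, 2), bool)), truth, 0.5)
        assert not report.precision_defined
        assert np.isnan(report.precision)
        assert report.to_dict()["precision"] is None

    def test_unlabeled_pixels_excluded(self):
        truth = np.array([[0, 0, 2, 1]], dtype=np.uint8)
        pred = np.array([[True, True, True, False]])
        report = evaluate(self._map_from(pred), truth, 0.5)
        assert (report.tp, report.fp, report.fn, report.tn) == (1, 0, 0, 1)

    def test_no_labeled_pixels_raises(self):
        with pytest.raises(ValueError):
            evaluate(self._map_from(np.zeros((2, 2), bool)),
                     np.zeros((2, 2), dtype=np.uint8), 0.5)

    def test_lesion_recall_on_synthetic_fixture(
        self, trained_model, small_stack, small_case
    ):
        prob = predict_probability(trained_model, small_stack)
        report = evaluate(prob, small_case.truth_mask, 0.5)
        assert report.recall > 0.8 and report.precision > 0.8
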