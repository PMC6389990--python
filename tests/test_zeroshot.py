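import numpy as np
import pandas as pd
import pytest

from semdecode.semantic_space import CoordinateModel, design_matrix
from semdecode.zeroshot import (
    compare_models,
    enumerate_trial_pairs,
    fit_mapping,
    leave_two_out_averaged,
    leave_two_out_single_trial,
    pair_decision,
    permutation_null,
    predict_activation,
    roi_decode,
)

from conftest import dataset_views


class TestFitMapping:
    def test_ols_recovers_generating_weights(self):
        rng = np.random.default_rng(0)
        W_true = rng.normal(size=(5, 3))
        X = rng.normal(size=(50, 5))
        Y = X @ W_true + 2.0
        m = fit_mapping(X, Y, lam=0.0)
        np.testing.assert_allclose(m.predict(X), Y, atol=1e-8)
        held = rng.normal(size=(4, 5))
        np.testing.assert_allclose(m.predict(held), held @ W_true + 2.0, atol=1e-8)

    def test_large_penalty_shrinks_to_training_mean(self):
        rng = np.random.default_rng(1)
        X, Y = rng.normal(size=(20, 6)), rng.normal(size=(20, 2))
        m = fit_mapping(X, Y, lam=1e12)
        np.testing.assert_allclose(
            m.predict(rng.normal(size=(3, 6))),
            np.tile(Y.mean(axis=0), (3, 1)),
            atol=1e-6,
        )

    def test_gcv_generalizes_on_noise_free_forward_model(self):
        # noise-free linear image of coordinates, more items than dimensions
        # (otherwise held-out coordinates lie outside the training span)
        rng = np.random.default_rng(6)
        S = rng.normal(size=(40, 6))
        W_fwd = rng.normal(size=(25, 6))
        X = S @ W_fwd.T
        m = fit_mapping(X[:-1], S[:-1], lam="gcv")
        np.testing.assert_allclose(m.predict(X[[-1]])[0], S[-1], atol=1e-6)

    def test_nonfinite_input_rejected(self):
        X = np.ones((4, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_mapping(X, np.ones((4, 1)), lam=1.0)

    def test_dual_and_primal_solutions_agree(self):
        rng = np.random.default_rng(2)
        X, Y = rng.normal(size=(15, 40)), rng.normal(size=(15, 3))
        dual = fit_mapping(X, Y, lam=2.5)  # V > n path
        A = ((X - X.mean(0)) / X.std(0)).T
        primal_W = np.linalg.solve(A @ A.T + 2.5 * np.eye(40), A @ (Y - Y.mean(0)))
        np.testing.assert_allclose(dual.weights, primal_W, atol=1e-8)


class TestPairDecision:
    def test_perfect_predictions_correct(self):
        t1, t2 = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        assert pair_decision(t1, t2, t1, t2).decision == "correct"

    def test_swapped_predictions_incorrect(self):
        t1, t2 = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        assert pair_decision(t2, t1, t1, t2).decision == "incorrect"

    def test_identical_truths_tie(self):
        t = np.array([1.0, 1.0])
        p1, p2 = np.array([2.0, 0.0]), np.array([0.0, 2.0])
        out = pair_decision(p1, p2, t, t)
        assert out.decision == "tie" and out.score == 0.5

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            pair_decision(np.zeros(2), np.ones(2), np.ones(2), np.ones(2))

    def test_symmetric_under_item_swap(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            p1, p2, t1, t2 = rng.normal(size=(4, 5))
            a = pair_decision(p1, p2, t1, t2).decision
            b = pair_decision(p2, p1, t2, t1).decision
            assert a == b

    def test_distances_within_cosine_range(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            out = pair_decision(*rng.normal(size=(4, 6)))
            assert all(0.0 <= d <= 2.0 for d in out.distances)


class TestLeaveTwoOutAveraged:
    def test_fold_count_is_n_choose_2(self, tiny_dataset):
        targets, cats, reps, Y = dataset_views(tiny_dataset)
        res = leave_two_out_averaged(reps, Y, categories=cats, targets=targets, k=30)
        n = len(targets)
        assert res.n_pairs == n * (n - 1) // 2

    def test_noise_free_accuracy_is_perfect(self, noise_free_dataset):
        targets, cats, reps, Y = dataset_views(noise_free_dataset)
        res = leave_two_out_averaged(reps, Y, categories=cats, targets=targets, k=30)
        assert res.overall_accuracy == 100.0

    def test_within_and_across_strata_partition_pairs(self, tiny_dataset):
        targets, cats, reps, Y = dataset_views(tiny_dataset)
        res = leave_two_out_averaged(reps, Y, categories=cats, targets=targets, k=30)
        counts = res.counts()
        assert counts["within"] == 4 * 1  # 4 categories x C(2,2 items)
        assert counts["within"] + counts["across"] == res.n_pairs


class TestSingleTrial:
    def test_pair_enumeration_structure(self, tiny_dataset):
        counts = enumerate_trial_pairs(tiny_dataset.trials)
        n = len(tiny_dataset.trials)
        assert counts["total"] == n * (n - 1) // 2
        assert counts["same_target"] == 8 * 15
        assert counts["distinct_target"] == counts["target_pairs"] * 36

    def test_training_excludes_all_repetitions_of_test_targets(self, tiny_dataset):
        """Zero-shot guarantee: 6+6 trials of the held-out pair never train."""
        ds = tiny_dataset
        Y = design_matrix(ds.trials, CoordinateModel.TARGET, ds.norms, ds.keyword_map, ds.space)
        res = leave_two_out_single_trial(
            ds.beta_stacks[0].betas, ds.trials, Y, lam=1.0,
            target_pairs=[(ds.norms.targets[0], ds.norms.targets[1])],
            include_same_target=False,
        )
        assert res.n_pairs == 36  # 6 x 6 trial pairs share one fitted mapping

    def test_same_target_pairs_tie_under_target_model(self, tiny_dataset):
        ds = tiny_dataset
        Y = design_matrix(ds.trials, CoordinateModel.TARGET, ds.norms, ds.keyword_map, ds.space)
        res = leave_two_out_single_trial(
            ds.beta_stacks[0].betas, ds.trials, Y, lam=1.0, target_pairs=[]
        )
        same = res.pairs[res.pairs["relation"] == "same-target"]
        assert len(same) == 8 * 15 and (same["decision"] == "tie").all()
        assert res.same_target_accuracy == 50.0

    def test_noise_free_single_trial_perfect(self, noise_free_dataset):
        ds = noise_free_dataset
        Y = design_matrix(
            ds.trials, CoordinateModel.ALL_FEATURES, ds.norms, ds.keyword_map, ds.space
        )
        res = leave_two_out_single_trial(
            ds.beta_stacks[0].betas, ds.trials, Y, lam=1.0, include_same_target=False
        )
        assert res.overall_accuracy == 100.0


class TestPermutationNull:
    def test_null_centers_at_chance(self, tiny_dataset):
        targets, cats, reps, Y = dataset_views(tiny_dataset)
        null = permutation_null(
            reps, Y, n_iter=40, seed=7, analysis="averaged", categories=cats, k=30
        )
        se = null.accuracies.std(ddof=1) / np.sqrt(null.n_iter)
        assert abs(null.mean - 50.0) < max(3 * se, 5.0)

    def test_threshold_at_least_median_and_deterministic(self, tiny_dataset):
        targets, cats, reps, Y = dataset_views(tiny_dataset)
        kwargs = dict(analysis="averaged", categories=cats, k=30)
        a = permutation_null(reps, Y, 10, 3, **kwargs)
        b = permutation_null(reps, Y, 10, 3, **kwargs)
        assert a.threshold >= np.median(a.accuracies)
        np.testing.assert_array_equal(a.accuracies, b.accuracies)


class TestRoiDecode:
    def test_full_mask_equals_unselected_averaged(self, tiny_dataset):
        targets, cats, reps, Y = dataset_views(tiny_dataset)
        roi = np.arange(reps.shape[2])
        a = roi_decode(reps, roi, Y, categories=cats, targets=targets, lam=1.0)
        b = leave_two_out_averaged(reps, Y, categories=cats, targets=targets, k=None, lam=1.0)
        assert a.pairs["decision"].tolist() == b.pairs["decision"].tolist()

    def test_informative_roi_noise_free_is_perfect(self, noise_free_dataset):
        ds = noise_free_dataset
        targets, cats, reps, Y = dataset_views(ds)
        res = roi_decode(
            reps, ds.ground_truths[0].informative, Y, categories=cats, targets=targets
        )
        assert res.overall_accuracy == 100.0

    def test_empty_roi_rejected(self, tiny_dataset):
        targets, cats, reps, Y = dataset_views(tiny_dataset)
        with pytest.raises(ValueError):
            roi_decode(reps, np.array([], dtype=int), Y)


class TestPredictActivation:
    @pytest.fixture()
    def fitted(self, noise_free_dataset):
        targets, cats, reps, Y = dataset_views(noise_free_dataset)
        avg = reps.mean(axis=1)
        return fit_mapping(avg, Y, lam=1e-6), avg, Y

    def test_roundtrip_through_decoder(self, fitted):
        mapping, avg, Y = fitted
        pattern = predict_activation(mapping, Y[0])
        decoded = mapping.predict(pattern[None, :])[0]
        cos = decoded @ Y[0] / (np.linalg.norm(decoded) * np.linalg.norm(Y[0]))
        assert cos > 0.99

    def test_affine_linearity(self, fitted):
        mapping, _, Y = fitted
        a, b = Y[0], Y[1]
        lhs = predict_activation(mapping, a + b)
        rhs = (
            predict_activation(mapping, a)
            + predict_activation(mapping, b)
            - predict_activation(mapping, np.zeros_like(a))
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)

    def test_intercept_maps_to_mean_pattern(self, fitted):
        mapping, avg, _ = fitted
        np.testing.assert_allclose(
            predict_activation(mapping, mapping.intercept), avg.mean(axis=0), atol=1e-8
        )


class TestCompareModels:
    def test_identical_columns_t_zero_p_one(self):
        acc = pd.DataFrame({"a": [60.0, 70.0, 65.0], "b": [60.0, 70.0, 65.0]})
        row = compare_models(acc).iloc[0]
        assert row["t"] == 0.0 and row["p_bonferroni"] == 1.0

    def test_constant_offset_p_zero(self):
        acc = pd.DataFrame({"a": [61.0, 71.0], "b": [60.0, 70.0]})
        row = compare_models(acc).iloc[0]
        assert row["p"] == 0.0 and np.isinf(row["t"]) and row["t"] > 0

    def test_bonferroni_multiplier_is_pair_count(self):
        rng = np.random.default_rng(0)
        acc = pd.DataFrame(rng.normal(60, 5, size=(6, 6)), columns=list("abcdef"))
        table = compare_models(acc)
        assert len(table) == 15
        np.testing.assert_allclose(
            table["p_bonferroni"], np.minimum(1.0, table["p"] * 15)
        )

    def test_requires_two_subjects(self):
        with pytest.raises(ValueError):
            compare_models(pd.DataFrame({"a": [1.0], "b": [2.0]}))
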