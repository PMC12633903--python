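"""Metrics: hand-checked values, identities, bootstrap bands, U tests, k-fold."""

import numpy as np
import pytest

from cmfp.metrics import (
    confusion_metrics,
    error_metrics,
    evaluate_predictions,
    kfold_compare,
    mann_whitney_u,
    repeated_run_summary,
    roc_auc,
    roc_curve_ci,
)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_half(self):
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_four_point_example(self):
        """Brute force over the 4 positive-negative pairs gives 3/4."""
        assert roc_auc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([0.1, 0.2], [1, 1])

    def test_equals_rank_sum_identity(self):
        """AUC = U / (n_pos * n_neg) on 100 random instances."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(10, 40))
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            scores = rng.normal(size=n)
            u, _ = mann_whitney_u(scores[y == 1], scores[y == 0])
            n_pos, n_neg = int(y.sum()), int((1 - y).sum())
            assert roc_auc(scores, y) == pytest.approx(u / (n_pos * n_neg), abs=1e-12)


class TestConfusionMetrics:
    def test_hand_example(self):
        """TP=3, FN=1, TN=2, FP=2."""
        y = [1, 1, 1, 1, 0, 0, 0, 0]
        pred = [1, 1, 1, 0, 1, 1, 0, 0]
        rep = confusion_metrics(pred, y)
        assert (rep.tp, rep.fn, rep.tn, rep.fp) == (3, 1, 2, 2)
        assert rep.sen == pytest.approx(0.75)
        assert rep.spe == pytest.approx(0.5)
        assert rep.acc == pytest.approx(0.625)
        assert rep.f1 == pytest.approx(2 / 3)

    def test_perfect_and_inverted(self):
        y = [1, 0, 1, 0]
        perfect = confusion_metrics(y, y)
        assert (perfect.acc, perfect.sen, perfect.spe, perfect.f1) == (1, 1, 1, 1)
        inverted = confusion_metrics([0, 1, 0, 1], y)
        assert inverted.acc == 0.0

    def test_swapping_label_coding_swaps_sen_spe(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, size=30)
        pred = rng.integers(0, 2, size=30)
        rep = confusion_metrics(pred, y)
        flipped = confusion_metrics(1 - pred, 1 - y)
        assert flipped.sen == pytest.approx(rep.spe)
        assert flipped.spe == pytest.approx(rep.sen)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            confusion_metrics([], [])


class TestErrorMetrics:
    def test_exact_probabilities_zero_error(self):
        assert error_metrics([1.0, 0.0, 1.0], [1, 0, 1]) == (0.0, 0.0)

    def test_constant_half(self):
        mae, rmse = error_metrics([0.5] * 4, [1, 0, 1, 1])
        assert mae == 0.5 and rmse == 0.5

    def test_hand_arithmetic(self):
        mae, rmse = error_metrics([0.9, 0.2], [1, 0])
        assert mae == pytest.approx(0.15)
        assert rmse == pytest.approx(np.sqrt(0.025), abs=1e-12)

    def test_rmse_at_least_mae(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            eta = rng.uniform(size=15)
            y = rng.integers(0, 2, size=15)
            mae, rmse = error_metrics(eta, y)
            assert rmse >= mae - 1e-12


class TestRocBand:
    def _data(self, seed=0, n=60):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, size=n)
        scores = y + rng.normal(0, 0.8, size=n)
        return scores, y

    def test_perfect_data_band_collapses(self):
        y = np.array([0] * 20 + [1] * 20)
        scores = y.astype(float)
        band = roc_curve_ci(scores, y, n_boot=200, seed=0)
        np.testing.assert_array_equal(band.tpr[1:], 1.0)
        np.testing.assert_array_equal(band.lower[1:], 1.0)

    def test_same_seed_identical(self):
        scores, y = self._data()
        b1 = roc_curve_ci(scores, y, n_boot=150, seed=5)
        b2 = roc_curve_ci(scores, y, n_boot=150, seed=5)
        np.testing.assert_array_equal(b1.lower, b2.lower)
        np.testing.assert_array_equal(b1.upper, b2.upper)

    def test_band_contains_point_estimate(self):
        scores, y = self._data(seed=3)
        band = roc_curve_ci(scores, y, n_boot=400, seed=3)
        assert np.all(band.lower <= band.tpr + 1e-12)
        assert np.all(band.upper >= band.tpr - 1e-12)

    def test_small_n_boot_rejected(self):
        scores, y = self._data()
        with pytest.raises(ValueError, match="n_boot"):
            roc_curve_ci(scores, y, n_boot=50)


class TestMannWhitney:
    def test_identical_constant_samples_half_u(self):
        u, _ = mann_whitney_u([1.0] * 4, [1.0] * 5)
        assert u == 4 * 5 / 2

    def test_fully_separated_three_vs_three_exact_p(self):
        """2 extreme arrangements out of C(6,3)=20 -> two-sided p = 0.1."""
        u, p = mann_whitney_u([10.0, 11.0, 12.0], [1.0, 2.0, 3.0])
        assert u == 9.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_u_complement_identity(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=8), rng.normal(size=11)
        u_ab, _ = mann_whitney_u(a, b)
        u_ba, _ = mann_whitney_u(b, a)
        assert u_ab + u_ba == len(a) * len(b)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney_u([], [1.0])


class TestRepeatedRunSummary:
    def test_constant_values(self):
        s = repeated_run_summary([0.7, 0.7, 0.7], "auc")
        assert s.mean == pytest.approx(0.7)
        assert s.variance == pytest.approx(0.0, abs=1e-30)

    def test_two_point_example(self):
        s = repeated_run_summary([0.0, 1.0])
        assert (s.mean, s.variance) == (0.5, 0.25)

    def test_matches_direct_recomputation(self, tmp_path):
        """8 seeded values round-tripped through CSV summarise identically."""
        import pandas as pd

        rng = np.random.default_rng(6)
        values = rng.uniform(0.4, 0.9, size=8)
        path = tmp_path / "runs.csv"
        pd.DataFrame({"auc": values}).to_csv(path, index=False)
        back = pd.read_csv(path)["auc"].to_numpy()
        s = repeated_run_summary(back, "auc")
        assert s.mean == pytest.approx(float(np.mean(values)))
        assert s.variance == pytest.approx(float(np.var(values)))

    def test_single_run_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            repeated_run_summary([0.5])


class TestKfoldCompare:
    def test_duplicate_learner_identical_rows(self, small_two_modal_cohort):
        cohort, _ = small_two_modal_cohort
        table = kfold_compare(
            cohort, ["naive_bayes", "naive_bayes"], k=3, seed=0, epochs=2,
            pair=("modA", "modB"),
        )
        assert len(table) == 2
        np.testing.assert_array_equal(table.iloc[0].values, table.iloc[1].values)

    def test_reproducible_under_seed(self, small_two_modal_cohort):
        cohort, _ = small_two_modal_cohort
        kwargs = dict(k=3, seed=1, epochs=2, pair=("modA", "modB"))
        t1 = kfold_compare(cohort, ["decision_tree"], **kwargs)
        t2 = kfold_compare(cohort, ["decision_tree"], **kwargs)
        np.testing.assert_array_equal(t1.values, t2.values)

    def test_separable_cohort_high_accuracy(self):
        """A nearly noiseless cohort should be easy for every learner."""
        from cmfp.synthetic import ModalitySpec, SyntheticParams, generate_cohort

        params = SyntheticParams(
            n=96, n_pos=48, shared_weight=1.0,
            modalities={
                "modA": ModalitySpec(4, 2, loading=1.0, noise_sd=0.05,
                                     private_weight=0.0),
                "modB": ModalitySpec(4, 2, loading=1.0, noise_sd=0.05,
                                     private_weight=0.0),
            },
        )
        cohort, _ = generate_cohort(params, seed=9)
        table = kfold_compare(
            cohort, ["adaboost", "logistic_regression", "knn"], k=4, seed=2,
            epochs=2, pair=("modA", "modB"),
        )
        assert (table["acc"] >= 0.9).all()

    def test_k_exceeding_class_size_rejected(self, small_two_modal_cohort):
        cohort, _ = small_two_modal_cohort
        with pytest.raises(ValueError, match="class size"):
            kfold_compare(cohort, ["knn"], k=50, pair=("modA", "modB"))


class TestEvaluatePredictions:
    def test_combines_all_metrics(self):
        y = [1, 1, 0, 0]
        rep = evaluate_predictions([1, 0, 0, 0], [0.9, 0.4, 0.3, 0.2], y)
        assert rep.acc == 0.75
        assert rep.auc == 1.0
        assert rep.mae == pytest.approx((0.1 + 0.6 + 0.3 + 0.2) / 4)
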