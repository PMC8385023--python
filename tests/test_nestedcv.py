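"""Nested-CV SVM classification: metrics, threshold choice, major features,
train/test hygiene, and performance comparison."""

import numpy as np
import pandas as pd
import pytest

from neurostab import (
    CVPerformance,
    compare_performance,
    compute_metrics,
    major_features,
    nested_cv,
    select_best_threshold,
)


class TestComputeMetrics:
    def test_definitional_arithmetic_at_55_43(self):
        # TP=40 FN=15 (positive n=55), TN=30 FP=13 (negative n=43)
        y = np.array(["p"] * 55 + ["n"] * 43)
        pred = np.array(["p"] * 40 + ["n"] * 15 + ["n"] * 30 + ["p"] * 13)
        m = compute_metrics(y, pred, np.linspace(0, 1, 98), "p")
        assert m["sensitivity"] == pytest.approx(40 / 55, abs=1e-12)
        assert m["specificity"] == pytest.approx(30 / 43, abs=1e-12)
        assert m["sensitivity"] == pytest.approx(0.727, abs=5e-4)
        assert m["specificity"] == pytest.approx(0.698, abs=5e-4)

    def test_perfect_scores_auc_one(self):
        y = np.array([0, 0, 1, 1])
        m = compute_metrics(y, y, np.array([0.1, 0.2, 0.8, 0.9]), 1)
        assert m["auc"] == 1.0

    def test_constant_scores_auc_half(self, rng):
        y = rng.integers(0, 2, 30)
        m = compute_metrics(y, y, np.zeros(30), 1)
        assert m["auc"] == 0.5

    def test_accuracy_identity(self, rng):
        y = rng.integers(0, 2, 200)
        pred = rng.integers(0, 2, 200)
        m = compute_metrics(y, pred, rng.normal(size=200), 1)
        n_pos, n_neg = (y == 1).sum(), (y == 0).sum()
        expected = (m["sensitivity"] * n_pos + m["specificity"] * n_neg) / 200
        assert m["accuracy"] == pytest.approx(expected, abs=1e-12)

    def test_rank_auc_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        y = rng.integers(0, 2, 150)
        scores = np.round(rng.normal(size=150), 1)  # induce ties
        m = compute_metrics(y, (scores > 0).astype(int), scores, 1)
        assert m["auc"] == pytest.approx(roc_auc_score(y, scores), abs=1e-12)

    def test_missing_class_raises(self):
        with pytest.raises(ValueError):
            compute_metrics(np.ones(5), np.ones(5), np.ones(5), 1)


class TestNestedCV:
    def test_separable_signal_high_accuracy(self, small_cohort):
        planted = small_cohort.truth["feature_index"].to_numpy()
        X = small_cohort.features.values[:, planted] * 2  # effect ~4 SD
        perf = nested_cv(X, small_cohort.labels, positive_class="high",
                         repeats=2, seed=1)
        assert perf.mean_accuracy > 0.95

    def test_determinism_same_seed(self, small_cohort):
        planted = small_cohort.truth["feature_index"].to_numpy()
        X = small_cohort.features.values[:, planted]
        a = nested_cv(X, small_cohort.labels, positive_class="high", repeats=2, seed=9)
        b = nested_cv(X, small_cohort.labels, positive_class="high", repeats=2, seed=9)
        assert a.per_repeat.equals(b.per_repeat)
        for fa, fb in zip(a.selection_log, b.selection_log):
            for sa, sb in zip(fa, fb):
                assert np.array_equal(sa, sb)

    def test_permuted_labels_near_chance(self, null_cohort, rng):
        """Fold-safe nested CV on permuted labels sits between chance (0.50)
        and the majority rate (55/98 = 0.561): with no class weighting the
        accuracy-tuned SVM may collapse to the majority class, so the honest
        null band is chance-to-majority, not a symmetric band around 0.5."""
        X = null_cohort.features.values[:, :30]
        y = rng.permutation(null_cohort.labels)
        perf = nested_cv(X, y, positive_class="high", repeats=3, seed=2)
        assert 0.38 <= perf.mean_accuracy <= 0.64

    def test_canary_test_rows_do_not_affect_training(self, small_cohort):
        """Train/test hygiene: corrupting the feature values of subjects while
        they sit in the test fold must leave the inner mRMR selections and the
        tuned hyperparameters of every fold unchanged."""
        planted = small_cohort.truth["feature_index"].to_numpy()
        X = small_cohort.features.values[:, planted]
        y = small_cohort.labels
        base = nested_cv(X, y, positive_class="high", repeats=1, seed=3)
        # corrupt one subject's features; splits depend only on y and are
        # unchanged, so folds where the subject is in test must match exactly
        from sklearn.model_selection import StratifiedKFold
        from neurostab.nestedcv import _repeat_seeds

        rs = _repeat_seeds(3, 1)[0]
        splits = list(StratifiedKFold(3, shuffle=True, random_state=rs).split(X, y))
        victim = splits[0][1][0]  # in the test fold of outer fold 0
        X2 = X.copy()
        X2[victim] = 1e3
        alt = nested_cv(X2, y, positive_class="high", repeats=1, seed=3)
        assert np.array_equal(base.selection_log[0][0], alt.selection_log[0][0])
        assert base.tuning_log[0][0] == alt.tuning_log[0][0]

    def test_too_few_subjects_per_class(self, rng):
        X = rng.normal(size=(5, 4))
        y = np.array([0, 0, 0, 1, 1])
        with pytest.raises(ValueError):
            nested_cv(X, y, positive_class=1, repeats=1, outer=3)


def _perf(accs, threshold=None):
    df = pd.DataFrame({"accuracy": accs, "sensitivity": accs,
                       "specificity": accs, "auc": accs})
    return CVPerformance(per_repeat=df, positive_class="high", threshold=threshold)


class TestBestThreshold:
    def test_highest_mean_accuracy_wins(self):
        res = {500: _perf([0.71, 0.71]), 750: _perf([0.736, 0.736])}
        assert select_best_threshold(res) == 750

    def test_single_threshold_returned(self):
        assert select_best_threshold({300: _perf([0.6])}) == 300

    def test_tie_prefers_larger_threshold(self):
        res = {500: _perf([0.70, 0.70]), 700: _perf([0.70, 0.70])}
        assert select_best_threshold(res) == 700


def _log_perf(log, positive="high"):
    n = len(log)
    df = pd.DataFrame({"accuracy": [0.7] * n, "sensitivity": [0.7] * n,
                       "specificity": [0.7] * n, "auc": [0.7] * n})
    return CVPerformance(per_repeat=df, positive_class=positive, selection_log=log)


class TestMajorFeatures:
    def test_always_selected_feature_included(self):
        log = [[np.array([0, 1])] * 3 for _ in range(100)]
        out = major_features(_log_perf(log))
        assert out["column"].tolist() == [0, 1]
        assert out["repeat_count"].tolist() == [100, 100]

    def test_exactly_ninety_repeats_excluded(self):
        # feature 1 selected (majority of folds) in exactly 90 of 100 repeats
        log = [[np.array([0, 1])] * 3 for _ in range(90)]
        log += [[np.array([0])] * 3 for _ in range(10)]
        out = major_features(_log_perf(log))
        assert out["column"].tolist() == [0]  # strict > 90

    def test_majority_fold_rule(self):
        # selected in only 1 of 3 folds per repeat: not counted under majority
        log = [[np.array([0]), np.array([1]), np.array([1])] for _ in range(100)]
        out = major_features(_log_perf(log))
        assert out["column"].tolist() == [1]

    def test_direction_matches_group_means(self, small_cohort):
        planted = small_cohort.truth["feature_index"].to_numpy()
        X = small_cohort.features.values[:, planted]
        log = [[np.arange(len(planted))] * 3 for _ in range(100)]
        out = major_features(_log_perf(log), X=X, y=small_cohort.labels)
        expected = np.where(small_cohort.truth["sign"] > 0, "+", "-")
        assert out["direction"].tolist() == expected.tolist()

    def test_empty_log_raises(self):
        with pytest.raises(ValueError):
            major_features(_log_perf([]))


class TestComparePerformance:
    def test_identical_vectors_t_zero_p_one(self):
        a = _perf([0.7, 0.72, 0.74])
        b = _perf([0.7, 0.72, 0.74])
        t, p = compare_performance(a, b)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_large_effect_tiny_p(self, rng):
        a = _perf(0.7 + rng.normal(0, 1e-4, 100))
        b = _perf(0.8 + rng.normal(0, 1e-4, 100))
        _, p = compare_performance(a, b)
        assert p < 1e-10

    def test_antisymmetry(self, rng):
        a = _perf(rng.uniform(0.6, 0.8, 20))
        b = _perf(rng.uniform(0.6, 0.8, 20))
        t1, p1 = compare_performance(a, b)
        t2, p2 = compare_performance(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_zero_variance_both_raises(self):
        with pytest.raises(ValueError):
            compare_performance(_perf([0.7, 0.7]), _perf([0.8, 0.8]))
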