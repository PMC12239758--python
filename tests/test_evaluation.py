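"""Metric panel, stratified folds, aggregation and bootstrap intervals."""

import numpy as np
import pytest

from kmersig import (
    aggregate_cv,
    bootstrap_ci,
    confusion_and_rates,
    mcc,
    pr_auc,
    roc_auc,
    stratified_folds,
    youden_index,
)
from kmersig.evaluation import ConfusionMatrix, FoldResult
from kmersig.ensemble import compute_weights
from kmersig.errors import ParameterError, UndefinedMetricError


class TestStratifiedFolds:
    def test_balanced_cohort_gives_exact_folds(self):
        y = np.array([1] * 50 + [0] * 50)
        folds = stratified_folds(y, 5, seed=0)
        for _, va in folds:
            assert (y[va] == 1).sum() == 10
            assert (y[va] == 0).sum() == 10

    def test_remainders_spread_by_at_most_one(self):
        y = np.array([1] * 52 + [0] * 48)
        folds = stratified_folds(y, 5, seed=0)
        for _, va in folds:
            assert (y[va] == 1).sum() in (10, 11)
            assert (y[va] == 0).sum() in (9, 10)

    def test_partition_properties(self):
        y = np.array([1] * 23 + [0] * 31)
        folds = stratified_folds(y, 5, seed=3)
        all_val = np.concatenate([va for _, va in folds])
        assert sorted(all_val) == list(range(54))
        for tr, va in folds:
            assert set(tr).isdisjoint(va)
            assert len(tr) + len(va) == 54

    def test_class_smaller_than_folds(self):
        y = np.array([1] * 3 + [0] * 50)
        with pytest.raises(ParameterError, match="fewer folds"):
            stratified_folds(y, 5, seed=0)

    def test_deterministic_under_seed(self):
        y = np.array([1] * 20 + [0] * 20)
        a = stratified_folds(y, 5, seed=9)
        b = stratified_folds(y, 5, seed=9)
        for (t1, v1), (t2, v2) in zip(a, b):
            np.testing.assert_array_equal(v1, v2)


def brute_force_auc(scores, labels):
    """All-pairs Mann-Whitney oracle: concordant + half ties."""
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_worked_example(self):
        assert roc_auc([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0]) == 0.75

    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_tied_scores(self):
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc([0.2, 0.8], [1, 1])

    def test_matches_all_pairs_oracle(self, rng):
        """Rank-based AUC equals the exhaustive pair count on 500 random
        instances, including heavy ties, to 1e-12."""
        for _ in range(500):
            n = int(rng.integers(4, 51))
            y = np.zeros(n, dtype=int)
            y[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
            if y.sum() in (0, n):
                y[0] = 1 - y[0]
            scores = np.round(rng.random(n), int(rng.integers(1, 3)))  # induce ties
            assert abs(roc_auc(scores, y) - brute_force_auc(scores, y)) < 1e-12

    def test_score_complement_flips_auc(self, rng):
        n = 40
        y = rng.integers(0, 2, n)
        y[:2] = [0, 1]
        s = rng.random(n)
        assert abs(roc_auc(1 - s, y) - (1 - roc_auc(s, y))) < 1e-12


class TestPrAuc:
    def test_perfect_separation(self):
        assert pr_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_single_positive_ranked_first(self):
        assert pr_auc([0.99, 0.3, 0.2, 0.1], [1, 0, 0, 0]) == 1.0

    def test_no_positives_undefined(self):
        with pytest.raises(UndefinedMetricError):
            pr_auc([0.2, 0.8], [0, 0])

    def test_random_scores_approach_prevalence(self, rng):
        """With uninformative scores the PR AUC approaches the no-skill
        baseline, i.e. the class prevalence."""
        n = 20000
        prevalence = 0.3
        y = (rng.random(n) < prevalence).astype(int)
        s = rng.random(n)
        assert abs(pr_auc(s, y) - y.mean()) < 0.02


class TestConfusionAndRates:
    def test_worked_example(self):
        cm, rates = confusion_and_rates([1, 1, 1, 0, 0], [1, 1, 0, 0, 0])
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (2, 1, 2, 0)
        assert rates["precision"] == pytest.approx(2 / 3)
        assert rates["recall"] == 1.0
        assert rates["specificity"] == pytest.approx(2 / 3)
        assert rates["accuracy"] == pytest.approx(0.8)
        assert rates["f1"] == pytest.approx(0.8)
        assert rates["undefined"] == []

    def test_all_correct(self):
        _, rates = confusion_and_rates([1, 0, 1], [1, 0, 1])
        for m in ("accuracy", "precision", "recall", "specificity", "f1"):
            assert rates[m] == 1.0

    def test_no_predicted_positives_flagged(self):
        cm, rates = confusion_and_rates([0, 0, 0], [1, 0, 0])
        assert rates["precision"] == 0.0
        assert "precision" in rates["undefined"]
        assert rates["recall"] == 0.0

    def test_totals_match_fold_size(self, rng):
        y = rng.integers(0, 2, 37)
        yhat = rng.integers(0, 2, 37)
        cm, _ = confusion_and_rates(yhat, y)
        assert cm.total == 37

    def test_length_mismatch(self):
        with pytest.raises(ParameterError):
            confusion_and_rates([1, 0], [1, 0, 1])


class TestMcc:
    def test_worked_example(self):
        assert mcc(ConfusionMatrix(2, 1, 2, 0)) == pytest.approx(4 / 6)

    def test_perfect_and_inverted(self):
        assert mcc(ConfusionMatrix(5, 0, 5, 0)) == 1.0
        assert mcc(ConfusionMatrix(0, 5, 0, 5)) == -1.0

    def test_zero_factor_convention(self):
        assert mcc(ConfusionMatrix(0, 0, 3, 2)) == 0.0


class TestYouden:
    def test_worked_example(self):
        assert youden_index([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0]) == 0.5

    def test_perfect_separation(self):
        assert youden_index([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_tied(self):
        assert youden_index([0.4] * 4, [1, 0, 1, 0]) == 0.0

    def test_equals_exhaustive_threshold_sweep(self, rng):
        """Max TPR − FPR from the ROC curve equals a brute-force sweep over
        every distinct threshold."""
        for _ in range(50):
            n = 30
            y = rng.integers(0, 2, n)
            y[:2] = [0, 1]
            s = np.round(rng.random(n), 2)
            best = 0.0
            for t in np.unique(s):
                pred = (s >= t).astype(int)
                tpr = ((pred == 1) & (y == 1)).sum() / (y == 1).sum()
                fpr = ((pred == 1) & (y == 0)).sum() / (y == 0).sum()
                best = max(best, tpr - fpr)
            assert abs(youden_index(s, y) - best) < 1e-12


def _fold(y, scores, idx):
    hard = (np.asarray(scores) > 0.5).astype(int)
    return FoldResult(
        fold_index=idx,
        train_ids=[],
        val_ids=[f"s{idx}_{i}" for i in range(len(y))],
        y_true=np.asarray(y),
        model_scores={"M": np.asarray(scores, float)},
        model_labels={"M": hard},
        weights=compute_weights([0.8, 0.8]),
        n_selected=2,
        effective_dims=2,
    )


class TestAggregateCv:
    def test_identical_folds_have_zero_sd(self):
        y = [1, 1, 0, 0]
        s = [0.9, 0.4, 0.6, 0.1]
        report = aggregate_cv([_fold(y, s, 1), _fold(y, s, 2)], bootstrap_reps=0)
        block = report.models["M"]["fold_mean"]
        for m in block.values():
            assert m["sd"] == 0.0

    def test_mean_and_population_sd(self):
        # fold AUCs 0.6 and 0.8 by construction
        f1 = _fold([1, 1, 0, 0, 0, 1, 0, 1, 1, 0],
                   [0.9, 0.8, 0.7, 0.6, 0.55, 0.5, 0.4, 0.3, 0.2, 0.1], 1)
        f2 = _fold([1, 1, 1, 0, 1, 0, 1, 0, 0, 0],
                   [0.9, 0.8, 0.7, 0.6, 0.55, 0.5, 0.4, 0.3, 0.2, 0.1], 2)
        a1 = roc_auc(f1.model_scores["M"], f1.y_true)
        a2 = roc_auc(f2.model_scores["M"], f2.y_true)
        report = aggregate_cv([f1, f2], bootstrap_reps=0)
        got = report.models["M"]["fold_mean"]["roc_auc"]
        assert got["mean"] == pytest.approx((a1 + a2) / 2)
        assert got["sd"] == pytest.approx(abs(a1 - a2) / 2)  # population SD of 2 values

    def test_mean_roc_of_identical_folds_is_the_curve(self):
        y = [1, 1, 0, 0]
        s = [0.9, 0.8, 0.3, 0.2]
        report = aggregate_cv([_fold(y, s, 1), _fold(y, s, 2)], bootstrap_reps=0)
        roc = report.models["M"]["mean_roc"]
        assert np.allclose(roc["tpr_sd"], 0.0)
        assert roc["tpr_mean"][-1] == 1.0

    def test_confusion_averaged_elementwise(self):
        f1 = _fold([1, 0], [0.9, 0.8], 1)  # TP1 FP1
        f2 = _fold([1, 0], [0.9, 0.2], 2)  # TP1 TN1
        report = aggregate_cv([f1, f2], bootstrap_reps=0)
        cm = report.models["M"]["confusion_mean"]
        assert cm == {"TP": 1.0, "FP": 0.5, "TN": 0.5, "FN": 0.0}

    def test_empty_fold_list(self):
        with pytest.raises(ParameterError):
            aggregate_cv([])


class TestBootstrapCi:
    def test_degenerate_scores_zero_width(self):
        lo, hi = bootstrap_ci([0.5] * 20, [1, 0] * 10, roc_auc, reps=200, seed=0)
        assert lo == hi == 0.5

    def test_interval_contains_point_estimate(self, rng):
        n = 60
        y = rng.integers(0, 2, n)
        y[:2] = [0, 1]
        s = rng.random(n) + 0.5 * y
        lo, hi = bootstrap_ci(s, y, roc_auc, reps=500, seed=1)
        point = roc_auc(s, y)
        assert lo <= point <= hi

    def test_deterministic_under_seed(self, rng):
        y = np.array([1, 0] * 15)
        s = rng.random(30)
        assert bootstrap_ci(s, y, roc_auc, reps=100, seed=5) == bootstrap_ci(
            s, y, roc_auc, reps=100, seed=5
        )

    def test_coverage_near_nominal(self, rng):
        """Percentile interval covers the true AUC at roughly the nominal 95%
        rate over repeated datasets drawn from a known binormal model."""
        mu = 1.0
        true_auc = 0.7602499389065233  # Phi(mu/sqrt(2)) for the binormal model
        n = 80
        covered = 0
        reps = 300
        for _ in range(reps):
            y = np.array([0] * (n // 2) + [1] * (n // 2))
            s = rng.standard_normal(n) + mu * y
            lo, hi = bootstrap_ci(s, y, roc_auc, reps=300, seed=int(rng.integers(2**31)))
            covered += lo <= true_auc <= hi
        assert abs(covered / reps - 0.95) < 0.05
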