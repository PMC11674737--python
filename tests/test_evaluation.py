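"""Folding, confusion metrics, AUC and cross-validated evaluation."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from nmrtune import (
    ConfusionCounts,
    evaluate_config,
    fitness_from_report,
    metric_accuracy,
    metric_f1,
    metric_precision,
    metric_recall,
    roc_auc,
    stratified_kfold,
)
from nmrtune._exceptions import ConfigurationError, EvaluationFailed
from nmrtune.codec import DecodedConfig
from nmrtune.evaluation import EvaluationReport


def brute_force_auc(scores, y):
    """Oracle: count concordant and tied positive-negative pairs."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestStratifiedKFold:
    def test_cohort_scale_partition(self):
        # 1232 samples split 819:413 into 10 folds
        y = np.array([1] * 819 + [0] * 413)
        plan = stratified_kfold(y, 10, seed=0)
        sizes = np.bincount(plan.fold_assignment)
        assert set(sizes.tolist()) <= {123, 124}
        assert sizes.sum() == 1232
        ones = [int(y[plan.fold_assignment == f].sum()) for f in range(10)]
        assert set(ones) <= {81, 82}

    def test_reproducible(self):
        y = np.array([0, 1] * 30)
        a = stratified_kfold(y, 5, seed=4)
        b = stratified_kfold(y, 5, seed=4)
        assert np.array_equal(a.fold_assignment, b.fold_assignment)

    def test_class_smaller_than_k(self):
        y = np.array([0] * 3 + [1] * 50)
        with pytest.raises(ConfigurationError):
            stratified_kfold(y, 5, seed=0)


class TestConfusionMetrics:
    def test_worked_example(self):
        c = ConfusionCounts(TP=90, TN=10, FP=5, FN=5)
        assert metric_accuracy(c) == pytest.approx(100 / 110)
        assert metric_precision(c) == pytest.approx(90 / 95)
        assert metric_recall(c) == pytest.approx(90 / 95)
        assert metric_f1(c) == pytest.approx(180 / 190)

    def test_f1_equals_common_value_when_p_equals_r(self):
        c = ConfusionCounts(TP=30, TN=50, FP=10, FN=10)
        assert metric_precision(c) == metric_recall(c)
        assert metric_f1(c) == pytest.approx(metric_precision(c))

    def test_f1_identity_between_forms(self):
        # harmonic-mean form == 2TP/(2TP+FP+FN) on random tables
        rng = np.random.default_rng(0)
        for _ in range(1000):
            tp, tn, fp, fn = rng.integers(0, 200, size=4)
            if tp + fp == 0 or tp + fn == 0 or tp + tn + fp + fn == 0:
                continue
            c = ConfusionCounts(TP=int(tp), TN=int(tn), FP=int(fp), FN=int(fn))
            p, r = metric_precision(c), metric_recall(c)
            harmonic = 0.0 if p + r == 0 else 2 * p * r / (p + r)
            assert abs(metric_f1(c) - harmonic) < 1e-12

    def test_zero_denominator_convention(self):
        c = ConfusionCounts(TP=0, TN=10, FP=0, FN=0)
        assert metric_precision(c) == 0.0
        c = ConfusionCounts(TP=0, TN=10, FP=5, FN=0)
        assert metric_recall(c) == 0.0

    def test_majority_constant_prediction_accuracy_is_prevalence(self):
        # predicting "malignant" for everyone on an 819:413 cohort
        y = np.array([1] * 819 + [0] * 413)
        c = ConfusionCounts.from_predictions(y, np.ones_like(y))
        assert metric_accuracy(c) == pytest.approx(819 / 1232)
        assert round(metric_accuracy(c), 4) == 0.6648


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1])) == 1.0

    def test_all_tied(self):
        assert roc_auc(np.full(10, 0.5), np.array([0, 1] * 5)) == 0.5

    def test_pair_count_example(self):
        # 3 concordant of 4 positive-negative pairs
        auc = roc_auc(np.array([0.1, 0.4, 0.35, 0.8]), np.array([0, 0, 1, 1]))
        assert auc == pytest.approx(0.75)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))

    def test_matches_pair_count_and_trapezoid_oracles(self):
        rng = np.random.default_rng(3)
        for n in (20, 97, 200):
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            scores = np.round(rng.random(n), 2)  # coarse grid forces ties
            ours = roc_auc(scores, y)
            assert ours == pytest.approx(brute_force_auc(scores, y), abs=1e-12)
            assert ours == pytest.approx(roc_auc_score(y, scores), abs=1e-12)


class TestEvaluateConfig:
    def test_full_mask_equals_no_mask(self, small_planted, small_plan):
        dataset, _ = small_planted
        no_mask = evaluate_config(dataset, DecodedConfig(params={}), "decision_tree", small_plan)
        full = evaluate_config(
            dataset,
            DecodedConfig(params={}, feature_mask=np.ones(dataset.n_features, dtype=bool)),
            "decision_tree",
            small_plan,
        )
        assert no_mask.confusion == full.confusion
        assert no_mask.accuracy == full.accuracy

    def test_bit_reproducible(self, small_planted, small_plan):
        dataset, _ = small_planted
        decoded = DecodedConfig(params={"n_neighbors": 7})
        a = evaluate_config(dataset, decoded, "knn", small_plan)
        b = evaluate_config(dataset, decoded, "knn", small_plan)
        assert a.confusion == b.confusion
        assert np.array_equal(a.scores, b.scores)

    def test_pooled_counts_sum_to_n(self, small_planted, small_plan):
        dataset, _ = small_planted
        report = evaluate_config(dataset, DecodedConfig(params={}), "knn", small_plan)
        assert report.confusion.total == dataset.n_samples
        assert len(report.per_fold_accuracy) == small_plan.k

    def test_metrics_consistent_with_confusion(self, small_planted, small_plan):
        dataset, _ = small_planted
        r = evaluate_config(dataset, DecodedConfig(params={}), "logistic_regression", small_plan)
        assert r.accuracy == metric_accuracy(r.confusion)
        assert r.precision == metric_precision(r.confusion)
        assert r.recall == metric_recall(r.confusion)
        assert r.f1 == metric_f1(r.confusion)

    def test_backend_rejection_raises_evaluation_failed(self, small_planted, small_plan):
        dataset, _ = small_planted
        bad = DecodedConfig(params={"penalty": "l1", "solver": "lbfgs"})
        with pytest.raises(EvaluationFailed):
            evaluate_config(dataset, bad, "logistic_regression", small_plan)

    def test_global_standardization_mode_runs(self, small_planted, small_plan):
        dataset, _ = small_planted
        r = evaluate_config(
            dataset, DecodedConfig(params={}), "knn", small_plan, standardize="global"
        )
        assert 0.0 <= r.accuracy <= 1.0


class TestFitness:
    def _report(self, accuracy, n_features):
        c = ConfusionCounts(TP=1, TN=1, FP=1, FN=1)
        return EvaluationReport(
            confusion=c, accuracy=accuracy, precision=0.5, recall=0.5, f1=0.5,
            auc=0.5, per_fold_accuracy=(accuracy,), n_features_used=n_features,
        )

    def test_accuracy_passthrough(self):
        assert fitness_from_report(self._report(0.8182, 18)) == 0.8182

    def test_two_level_tiebreak_prefers_fewer_features(self):
        lean = fitness_from_report(self._report(0.8, 13), mode="2level")
        fat = fitness_from_report(self._report(0.8, 18), mode="2level")
        assert lean > fat
        # the discount never flips a real accuracy difference
        assert fitness_from_report(self._report(0.8001, 18), mode="2level") > lean
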