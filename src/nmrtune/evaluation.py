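"""Cross-validated evaluation: folding, metrics, and the fitness contract.

A decoded classifier configuration is scored by stratified k-fold
cross-validation: per fold the standardizer (and optional oversampler)
see only training rows, the backend is fitted, and the held-out
predictions are pooled into a single confusion matrix and score vector
covering every sample exactly once.  Accuracy, precision, recall and F1
are computed from the pooled confusion counts; AUC uses the
probability interpretation (concordant pairs + half the ties).

The report depends only on ``(dataset, decoded, plan, seed)``, which
makes the derived fitness deterministic per genome — a requirement of
the greedy optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.preprocessing import StandardScaler

from ._exceptions import ConfigurationError, EvaluationFailed, LoaderError
from .backends import make_classifier, predict_scores
from .codec import DecodedConfig

__all__ = [
    "TabularDataset",
    "CVPlan",
    "ConfusionCounts",
    "EvaluationReport",
    "stratified_kfold",
    "metric_accuracy",
    "metric_precision",
    "metric_recall",
    "metric_f1",
    "roc_auc",
    "evaluate_config",
    "fitness_from_report",
]


@dataclass
class TabularDataset:
    """Feature matrix plus binary labels (0 = benign, 1 = malignant)."""

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple[str, ...]
    label_name: str = "Mal"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.feature_names = tuple(self.feature_names)
        if self.X.ndim != 2:
            raise LoaderError("X must be a 2-D matrix")
        if self.X.shape[0] != self.y.shape[0]:
            raise LoaderError("X and y row counts differ")
        if self.X.shape[1] != len(self.feature_names):
            raise LoaderError("feature_names length does not match X columns")
        if self.X.shape[1] < 1:
            raise LoaderError("dataset needs at least one feature")
        if np.isnan(self.X).any():
            raise LoaderError("dataset contains missing values")
        labels = np.unique(self.y)
        if not np.array_equal(labels, np.array([0, 1])):
            raise LoaderError(
                f"labels must be binary 0/1 with both classes present, got {labels.tolist()}"
            )

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class CVPlan:
    """A frozen fold assignment shared by all evaluations in one run."""

    k: int
    fold_assignment: np.ndarray  # per-sample fold index in [0, k)
    seed: int
    stratified: bool = True

    def folds(self):
        for f in range(self.k):
            test = self.fold_assignment == f
            yield np.flatnonzero(~test), np.flatnonzero(test)


def stratified_kfold(y: np.ndarray, k: int, seed: int, stratified: bool = True) -> CVPlan:
    """Build a k-fold plan; stratified folds keep per-fold class counts
    within one sample of the global ratio."""
    y = np.asarray(y, dtype=int)
    if k < 2:
        raise ConfigurationError(f"k must be >= 2, got {k}")
    if stratified:
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < k:
            raise ConfigurationError(
                f"smallest class has {counts.min()} members, fewer than k={k} folds"
            )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        if y.size < k:
            raise ConfigurationError("fewer samples than folds")
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(y.size, dtype=int)
    for f, (_, test_idx) in enumerate(splitter.split(np.zeros((y.size, 1)), y)):
        assignment[test_idx] = f
    return CVPlan(k=k, fold_assignment=assignment, seed=seed, stratified=stratified)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            TP=int(np.sum((y_true == 1) & (y_pred == 1))),
            TN=int(np.sum((y_true == 0) & (y_pred == 0))),
            FP=int(np.sum((y_true == 0) & (y_pred == 1))),
            FN=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


def _check_nonempty(c: ConfusionCounts) -> None:
    if c.total == 0:
        raise ValueError("empty confusion matrix")


def metric_accuracy(c: ConfusionCounts) -> float:
    _check_nonempty(c)
    return (c.TP + c.TN) / c.total


def metric_precision(c: ConfusionCounts) -> float:
    _check_nonempty(c)
    denom = c.TP + c.FP
    return c.TP / denom if denom else 0.0


def metric_recall(c: ConfusionCounts) -> float:
    _check_nonempty(c)
    denom = c.TP + c.FN
    return c.TP / denom if denom else 0.0


def metric_f1(c: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall, i.e. 2·TP / (2·TP + FP + FN)."""
    _check_nonempty(c)
    denom = 2 * c.TP + c.FP + c.FN
    return 2 * c.TP / denom if denom else 0.0


def roc_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC as P(score of random positive > score of random negative), ties
    counted half — the Mann–Whitney rank form, equal to trapezoidal ROC area."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)  # average ranks handle ties as half-wins
    rank_sum_pos = ranks[y == 1].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class EvaluationReport:
    """Pooled out-of-fold evaluation of one decoded configuration."""

    confusion: ConfusionCounts
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    per_fold_accuracy: tuple[float, ...]
    n_features_used: int
    classifier_id: str = ""
    scores: np.ndarray | None = field(default=None, repr=False)


def evaluate_config(
    dataset: TabularDataset,
    decoded: DecodedConfig,
    classifier_id: str,
    plan: CVPlan,
    oversampler=None,
    standardize: str = "per_fold",
) -> EvaluationReport:
    """Cross-validate one decoded configuration and pool the results.

    ``standardize`` is ``"per_fold"`` (z-score fitted on training rows of
    each fold; no leakage) or ``"global"`` (fitted once on the full data
    before splitting, mirroring pipelines that standardize up front).
    ``oversampler`` is an :class:`~nmrtune.imbalance.OversamplerConfig`
    or None; it touches training rows only.  Backend rejections raise
    :class:`EvaluationFailed` carrying the backend message.
    """
    if standardize not in ("per_fold", "global"):
        raise ConfigurationError(f"standardize must be 'per_fold' or 'global', got {standardize!r}")
    X, y = dataset.X, dataset.y
    if decoded.feature_mask.size:
        if decoded.feature_mask.size != dataset.n_features:
            raise ConfigurationError(
                f"feature mask length {decoded.feature_mask.size} != {dataset.n_features}"
            )
        X = X[:, decoded.feature_mask]
        n_used = decoded.n_features_used
    else:
        n_used = dataset.n_features

    if standardize == "global":
        X = StandardScaler().fit_transform(X)

    n = dataset.n_samples
    pooled_pred = np.empty(n, dtype=int)
    pooled_scores = np.empty(n, dtype=float)
    per_fold_acc = []

    for fold, (train_idx, test_idx) in enumerate(plan.folds()):
        X_train, y_train = X[train_idx], y[train_idx]
        X_test, y_test = X[test_idx], y[test_idx]
        if np.unique(y_train).size < 2:
            raise EvaluationFailed(f"fold {fold}: training rows contain one class only")
        if standardize == "per_fold":
            scaler = StandardScaler().fit(X_train)
            X_train = scaler.transform(X_train)
            X_test = scaler.transform(X_test)
        if oversampler is not None and getattr(oversampler, "method", "none") != "none":
            from .imbalance import oversample

            X_train, y_train = oversample(
                X_train, y_train, oversampler,
                rng=np.random.default_rng([oversampler.seed, fold]),
            )
        model = make_classifier(classifier_id, decoded.params, random_state=plan.seed)
        try:
            model.fit(X_train, y_train)
            preds = model.predict(X_test)
            scores = predict_scores(model, X_test)
        except EvaluationFailed:
            raise
        except Exception as exc:  # backend rejected the configuration
            raise EvaluationFailed(f"{classifier_id}: {exc}") from exc
        pooled_pred[test_idx] = preds
        pooled_scores[test_idx] = scores
        per_fold_acc.append(float(np.mean(preds == y_test)))

    confusion = ConfusionCounts.from_predictions(y, pooled_pred)
    return EvaluationReport(
        confusion=confusion,
        accuracy=metric_accuracy(confusion),
        precision=metric_precision(confusion),
        recall=metric_recall(confusion),
        f1=metric_f1(confusion),
        auc=roc_auc(pooled_scores, y),
        per_fold_accuracy=tuple(per_fold_acc),
        n_features_used=n_used,
        classifier_id=classifier_id,
        scores=pooled_scores,
    )


#: Per-feature fitness discount in 2-level mode.  Far below the accuracy
#: quantum 1/n for any realistic n, so it only breaks exact accuracy ties
#: in favour of smaller feature sets.
FEATURE_TIEBREAK = 1e-9


def fitness_from_report(report: EvaluationReport, mode: str = "1level") -> float:
    """Optimizer fitness: pooled accuracy; in 2-level mode exact accuracy
    ties are broken toward fewer features."""
    if mode == "2level":
        return report.accuracy - FEATURE_TIEBREAK * report.n_features_used
    return report.accuracy
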