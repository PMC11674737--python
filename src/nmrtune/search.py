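"""Scikit-learn-style hyperparameter search driven by the NMR metaheuristic.

:class:`NMRSearchCV` plays the role of ``GridSearchCV``: construct it
around one of the ten supported classifier ids, call ``fit(X, y)``, and
it searches the classifier's encoded hyperparameter space (optionally
extended with a per-feature include/exclude mask — 2-level mode) by
maximizing pooled cross-validated accuracy, then refits the best decoded
configuration on the full data for ``predict``/``predict_proba``.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from ._exceptions import EvaluationFailed
from .backends import make_classifier, predict_scores
from .codec import DecodedConfig, decode, preset_schema, schema_bounds
from .evaluation import (
    CVPlan,
    TabularDataset,
    evaluate_config,
    fitness_from_report,
    stratified_kfold,
)
from .imbalance import OversamplerConfig
from .optim import SENTINEL_WORST, NMRConfig, optimize

__all__ = ["NMRSearchCV", "make_cv_fitness", "evaluate_default"]


def make_cv_fitness(
    dataset: TabularDataset,
    classifier_id: str,
    schema,
    plan: CVPlan,
    mode: str = "1level",
    oversampler: OversamplerConfig | None = None,
    standardize: str = "per_fold",
    cache: dict | None = None,
):
    """Fitness closure mapping a genome to cross-validated accuracy.

    Decoding is piecewise constant, so results are memoised by decoded
    configuration; failed evaluations are cached as sentinel-worst so a
    rejected configuration is fitted only once per run.
    """
    cache = cache if cache is not None else {}

    def fitness(values: np.ndarray) -> float:
        decoded = decode(values, schema)
        key = decoded.cache_key()
        if key in cache:
            return cache[key]
        try:
            report = evaluate_config(
                dataset, decoded, classifier_id, plan,
                oversampler=oversampler, standardize=standardize,
            )
            score = fitness_from_report(report, mode)
        except EvaluationFailed:
            cache[key] = SENTINEL_WORST
            raise
        cache[key] = score
        return score

    return fitness


def evaluate_default(
    dataset: TabularDataset,
    classifier_id: str,
    plan: CVPlan,
    oversampler: OversamplerConfig | None = None,
    standardize: str = "per_fold",
):
    """Cross-validate the backend's library-default configuration on the
    full feature set (the no-optimization baseline)."""
    decoded = DecodedConfig(params={})
    return evaluate_config(
        dataset, decoded, classifier_id, plan,
        oversampler=oversampler, standardize=standardize,
    )


class NMRSearchCV(BaseEstimator, ClassifierMixin):
    """Hyperparameter (and optional feature-subset) search with the naked
    mole-rat metaheuristic, scored by stratified k-fold accuracy.

    Parameters
    ----------
    classifier : str
        One of the ten supported classifier ids (``"knn"``,
        ``"lightgbm"``, ``"xgboost"``, ...).
    select_features : bool
        False -> 1-level mode (hyperparameters only); True -> 2-level
        mode, appending one mask slot per feature to the genome.
    pop_size, epochs, pb, pm, breeder_fraction, levy_beta, levy_scale,
    crossover_prob : optimizer settings; see :class:`~nmrtune.optim.NMRConfig`.
    cv : int
        Fold count for the fixed cross-validation plan.
    stratified : bool
        Preserve class ratios across folds.
    oversample : str
        ``"none"``, ``"smote"`` or ``"adasyn"``; applied to training
        folds only.
    standardize : str
        ``"per_fold"`` (leakage-free) or ``"global"``.
    range_overrides : mapping, optional
        Per-gene search-range patches, e.g. ``{"n_estimators": {"hi": 100}}``.
    random_state : int
        Single seed fanned out to folds, optimizer and oversampler.

    Attributes
    ----------
    best_params_ : dict           decoded best hyperparameters
    support_ : ndarray of bool    selected-feature mask (all True in 1-level)
    best_score_ : float           pooled CV accuracy of the best genome
    best_report_ : EvaluationReport  full metrics of the best genome
    history_ : ndarray            monotone best-so-far fitness per epoch
    n_evaluations_ : int          total fitness evaluations spent
    """

    def __init__(
        self,
        classifier: str = "lightgbm",
        select_features: bool = False,
        pop_size: int = 20,
        epochs: int = 20,
        pb: float = 0.75,
        pm: float = 0.1,
        breeder_fraction: float = 0.2,
        levy_beta: float = 1.5,
        levy_scale: float | None = None,
        crossover_prob: float = 0.5,
        cv: int = 10,
        stratified: bool = True,
        oversample: str = "none",
        k_neighbors: int = 5,
        target_ratio: float = 1.0,
        standardize: str = "per_fold",
        range_overrides: Mapping | None = None,
        registry: Mapping | None = None,
        random_state: int = 0,
        n_jobs: int = 1,
    ):
        self.classifier = classifier
        self.select_features = select_features
        self.pop_size = pop_size
        self.epochs = epochs
        self.pb = pb
        self.pm = pm
        self.breeder_fraction = breeder_fraction
        self.levy_beta = levy_beta
        self.levy_scale = levy_scale
        self.crossover_prob = crossover_prob
        self.cv = cv
        self.stratified = stratified
        self.oversample = oversample
        self.k_neighbors = k_neighbors
        self.target_ratio = target_ratio
        self.standardize = standardize
        self.range_overrides = range_overrides
        self.registry = registry
        self.random_state = random_state
        self.n_jobs = n_jobs

    def _mode(self) -> str:
        return "2level" if self.select_features else "1level"

    def _oversampler(self) -> OversamplerConfig | None:
        if self.oversample == "none":
            return None
        return OversamplerConfig(
            method=self.oversample,
            k_neighbors=self.k_neighbors,
            target_ratio=self.target_ratio,
            seed=self.random_state,
        )

    def fit(self, X, y, feature_names=None):
        X, y = check_X_y(X, y, dtype=float)
        if feature_names is None:
            feature_names = tuple(f"x{i}" for i in range(X.shape[1]))
        dataset = TabularDataset(X=X, y=y, feature_names=feature_names)

        plan = stratified_kfold(dataset.y, self.cv, seed=self.random_state,
                                stratified=self.stratified)
        schema = preset_schema(
            self.classifier,
            n_features=dataset.n_features if self.select_features else 0,
            mode=self._mode(),
            registry=self.registry,
            overrides=self.range_overrides,
        )
        bounds = schema_bounds(schema)
        config = NMRConfig(
            pop_size=self.pop_size,
            epochs=self.epochs,
            pb=self.pb,
            pm=self.pm,
            breeder_fraction=self.breeder_fraction,
            levy_beta=self.levy_beta,
            levy_scale=self.levy_scale,
            crossover_prob=self.crossover_prob,
            seed=self.random_state,
        )
        cache: dict = {}
        fitness = make_cv_fitness(
            dataset, self.classifier, schema, plan,
            mode=self._mode(), oversampler=self._oversampler(),
            standardize=self.standardize, cache=cache,
        )
        result = optimize(fitness, bounds, config, n_jobs=self.n_jobs)

        decoded = decode(result.best_genome.values, schema)
        report = evaluate_config(
            dataset, decoded, self.classifier, plan,
            oversampler=self._oversampler(), standardize=self.standardize,
        )

        self.classes_ = np.array([0, 1])
        self.schema_ = schema
        self.plan_ = plan
        self.optimization_result_ = result
        self.best_genome_ = result.best_genome.values
        self.best_params_ = decoded.params
        self.support_ = (
            decoded.feature_mask
            if decoded.feature_mask.size
            else np.ones(dataset.n_features, dtype=bool)
        )
        self.best_score_ = report.accuracy
        self.best_report_ = report
        self.history_ = result.history
        self.n_evaluations_ = result.evaluations
        self.n_features_in_ = dataset.n_features

        # refit the winning configuration on the full data for prediction
        self.scaler_ = StandardScaler().fit(X[:, self.support_])
        self.best_estimator_ = make_classifier(
            self.classifier, decoded.params,
            random_state=self.random_state, need_proba=True,
        )
        self.best_estimator_.fit(self.scaler_.transform(X[:, self.support_]), y)
        return self

    def _transform(self, X):
        check_is_fitted(self, "best_estimator_")
        X = check_array(X, dtype=float)
        return self.scaler_.transform(X[:, self.support_])

    def predict(self, X):
        return self.best_estimator_.predict(self._transform(X))

    def predict_proba(self, X):
        return self.best_estimator_.predict_proba(self._transform(X))

    def decision_function(self, X):
        return predict_scores(self.best_estimator_, self._transform(X))
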