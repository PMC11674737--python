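"""Adapters constructing classifier backends from decoded hyperparameters.

Each of the ten supported classifiers is an established library estimator
(scikit-learn, XGBoost, LightGBM) behind a uniform fit/predict-scores
contract.  The adapters translate decoded parameter names where the
backend uses booster-native spellings and otherwise pass parameters
through untouched; combinations the backend rejects surface as fit-time
errors which the evaluation layer converts to an evaluation-failed
signal.
"""

from __future__ import annotations

from typing import Any, Mapping

import numpy as np
from sklearn.ensemble import (
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import NuSVC
from sklearn.tree import DecisionTreeClassifier, ExtraTreeClassifier

from ._exceptions import ConfigurationError

__all__ = ["make_classifier", "predict_scores"]


def _lightgbm_params(params: dict) -> dict:
    """Resolve booster-native aliases the way LightGBM itself prioritises:
    ``bagging_fraction``/``feature_fraction`` win over ``subsample``/
    ``colsample_bytree``; ``gamma`` maps to ``min_split_gain``;
    ``eval_metric`` only matters with a validation set and is dropped."""
    out = dict(params)
    out.pop("eval_metric", None)
    if "gamma" in out:
        out["min_split_gain"] = out.pop("gamma")
    if "bagging_fraction" in out:
        out["subsample"] = out.pop("bagging_fraction")
    if "feature_fraction" in out:
        out["colsample_bytree"] = out.pop("feature_fraction")
    return out


def _logistic_params(params: dict) -> dict:
    out = dict(params)
    # l1_ratio is meaningful only under the elasticnet penalty; elsewhere it
    # is a no-op that scikit-learn warns about.
    if out.get("penalty") != "elasticnet":
        out.pop("l1_ratio", None)
    return out


def make_classifier(
    classifier_id: str,
    params: Mapping[str, Any] | None = None,
    random_state: int = 0,
    need_proba: bool = False,
):
    """Instantiate an unfitted backend for ``classifier_id``.

    ``params`` is a decoded hyperparameter assignment; an empty mapping
    yields the library's default configuration.  ``need_proba`` requests
    probability output from backends where it is optional (NuSVM).
    """
    params = dict(params or {})
    if classifier_id == "decision_tree":
        return DecisionTreeClassifier(random_state=random_state, **params)
    if classifier_id == "extra_tree":
        return ExtraTreeClassifier(random_state=random_state, **params)
    if classifier_id == "gradient_boosting":
        return GradientBoostingClassifier(random_state=random_state, **params)
    if classifier_id == "knn":
        return KNeighborsClassifier(**params)
    if classifier_id == "lightgbm":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(
            random_state=random_state,
            n_jobs=1,
            verbose=-1,
            **_lightgbm_params(params),
        )
    if classifier_id == "logistic_regression":
        return LogisticRegression(random_state=random_state, **_logistic_params(params))
    if classifier_id == "nusvm":
        return NuSVC(random_state=random_state, probability=need_proba, **params)
    if classifier_id == "random_forest":
        return RandomForestClassifier(random_state=random_state, n_jobs=1, **params)
    if classifier_id == "xgboost":
        from xgboost import XGBClassifier

        return XGBClassifier(
            random_state=random_state,
            n_jobs=1,
            verbosity=0,
            eval_metric="logloss",
            **params,
        )
    if classifier_id == "extra_trees":
        return ExtraTreesClassifier(random_state=random_state, n_jobs=1, **params)
    raise ConfigurationError(f"unknown classifier id {classifier_id!r}")


def predict_scores(model, X: np.ndarray) -> np.ndarray:
    """Continuous scores for the positive (malignant) class.

    Probability of class 1 when the backend provides it, otherwise the
    decision-function margin; either is a valid ranking score for AUC.
    """
    if hasattr(model, "predict_proba"):
        try:
            return model.predict_proba(X)[:, 1]
        except AttributeError:
            pass
    return model.decision_function(X)
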