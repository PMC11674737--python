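"""Model-agnostic Shapley-value feature attribution.

The coalition value of a feature subset S is the model's mean score when
the features in S are pinned to the explained instance and the rest are
drawn from a background sample (marginal/interventional imputation).
For small feature counts the Shapley values are computed by exact
enumeration over all coalitions; otherwise by Monte-Carlo permutation
sampling: walk a random feature ordering, switching features one at a
time from a sampled background row to the instance, and average each
feature's marginal contribution.

Exact attributions satisfy the classical axioms — efficiency (values sum
to f(x) minus the base value), symmetry, dummy and linearity; the
Monte-Carlo estimator is unbiased for them.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._exceptions import ConfigurationError

__all__ = [
    "ShapleyConfig",
    "Attribution",
    "shapley_exact",
    "shapley_mc",
    "shapley_values",
    "global_importance",
]


@dataclass(frozen=True)
class ShapleyConfig:
    n_permutations: int = 200
    background_size: int = 100
    seed: int = 0
    exact_threshold: int = 12  # largest p for exact enumeration

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ConfigurationError("n_permutations must be >= 1")
        if self.background_size < 1:
            raise ConfigurationError("background_size must be >= 1")


@dataclass
class Attribution:
    """Per-feature Shapley values for one explained instance."""

    values: np.ndarray  # length p
    base_value: float  # expected model score over the background

    def efficiency_residual(self, fx: float) -> float:
        return float(abs(fx - self.base_value - self.values.sum()))


def _coalition_value(
    model_scores: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    background: np.ndarray,
    subset: tuple[int, ...],
) -> float:
    imputed = background.copy()
    if subset:
        imputed[:, list(subset)] = x[list(subset)]
    return float(np.mean(model_scores(imputed)))


def shapley_exact(
    model_scores: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    background: np.ndarray,
    exact_threshold: int = 12,
) -> Attribution:
    """Exact Shapley values by enumeration over all 2^p coalitions."""
    x = np.asarray(x, dtype=float)
    background = np.atleast_2d(np.asarray(background, dtype=float))
    p = x.size
    if p > exact_threshold:
        raise ConfigurationError(
            f"p={p} exceeds exact_threshold={exact_threshold}; use shapley_mc"
        )
    features = range(p)
    cache = {
        subset: _coalition_value(model_scores, x, background, subset)
        for size in range(p + 1)
        for subset in combinations(features, size)
    }
    values = np.zeros(p)
    for j in features:
        rest = [f for f in features if f != j]
        for size in range(p):
            weight = factorial(size) * factorial(p - size - 1) / factorial(p)
            for subset in combinations(rest, size):
                with_j = tuple(sorted(subset + (j,)))
                values[j] += weight * (cache[with_j] - cache[subset])
    return Attribution(values=values, base_value=cache[()])


def shapley_mc(
    model_scores: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    background: np.ndarray,
    config: ShapleyConfig = ShapleyConfig(),
) -> Attribution:
    """Permutation-sampling Shapley estimate.

    Per sampled ordering, features preceding position t come from the
    instance and the rest from one sampled background row; one vectorised
    model call per permutation scores the whole replacement walk.  The
    base value is the mean model score over the full background, so the
    efficiency residual shrinks as permutations accumulate.
    """
    x = np.asarray(x, dtype=float)
    background = np.atleast_2d(np.asarray(background, dtype=float))
    p = x.size
    rng = np.random.default_rng(config.seed)
    values = np.zeros(p)
    for _ in range(config.n_permutations):
        order = rng.permutation(p)
        b = background[rng.integers(background.shape[0])]
        walk = np.tile(b, (p + 1, 1))
        for t, j in enumerate(order):
            walk[t + 1:, j] = x[j]
        scores = np.asarray(model_scores(walk), dtype=float)
        values[order] += np.diff(scores)
    values /= config.n_permutations
    base = float(np.mean(model_scores(background)))
    return Attribution(values=values, base_value=base)


def shapley_values(
    model_scores: Callable[[np.ndarray], np.ndarray],
    X_explain: np.ndarray,
    background: np.ndarray,
    config: ShapleyConfig = ShapleyConfig(),
) -> tuple[np.ndarray, float]:
    """Attribute every row of ``X_explain``; exact when p allows, MC otherwise.

    Returns the (n, p) value matrix and the base value.
    """
    X_explain = np.atleast_2d(np.asarray(X_explain, dtype=float))
    p = X_explain.shape[1]
    rows = []
    base = 0.0
    for i, x in enumerate(X_explain):
        if p <= config.exact_threshold:
            att = shapley_exact(model_scores, x, background, config.exact_threshold)
        else:
            att = shapley_mc(
                model_scores, x, background,
                ShapleyConfig(
                    n_permutations=config.n_permutations,
                    background_size=config.background_size,
                    seed=config.seed + i,
                    exact_threshold=config.exact_threshold,
                ),
            )
        rows.append(att.values)
        base = att.base_value
    return np.vstack(rows), base


def global_importance(
    values: np.ndarray, feature_names: Sequence[str]
) -> pd.DataFrame:
    """Rank features by mean |Shapley value| over the explained instances.

    Ties keep the original feature order (stable sort).
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] < 1:
        raise ConfigurationError("need at least one attributed instance")
    mean_abs = np.abs(values).mean(axis=0)
    frame = pd.DataFrame({"feature": list(feature_names), "mean_abs_shap": mean_abs})
    frame = frame.sort_values("mean_abs_shap", ascending=False, kind="stable")
    frame["rank"] = np.arange(1, len(frame) + 1)
    return frame.reset_index(drop=True)
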