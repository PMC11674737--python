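"""Minority oversampling for imbalanced training folds: SMOTE and ADASYN.

Both methods create synthetic minority samples by interpolating between a
minority point and one of its k nearest minority neighbours:
``x_new = x_i + u * (x_nn - x_i)`` with ``u ~ U(0,1)``.  SMOTE picks
parents uniformly; ADASYN concentrates the synthetic budget on minority
points whose neighbourhoods (searched over *all* classes) are
majority-dominated, i.e. near the decision boundary.  Neighbour searches
run on z-scored features so no single scale dominates the Euclidean
distance; interpolation happens in the original feature space, so every
synthetic row is a convex combination of two real minority rows.

Only training folds are ever oversampled; held-out rows are untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from ._exceptions import ConfigurationError

logger = logging.getLogger("nmrtune.imbalance")

__all__ = ["OversamplerConfig", "smote", "adasyn", "oversample"]


@dataclass(frozen=True)
class OversamplerConfig:
    method: str = "none"  # "none" | "smote" | "adasyn"
    k_neighbors: int = 5
    target_ratio: float = 1.0  # minority:majority after augmentation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("none", "smote", "adasyn"):
            raise ConfigurationError(f"unknown oversampling method {self.method!r}")
        if self.k_neighbors < 1:
            raise ConfigurationError("k_neighbors must be positive")
        if not 0.0 < self.target_ratio <= 1.0:
            raise ConfigurationError("target_ratio must be in (0, 1]")


def _split_classes(y: np.ndarray) -> tuple[int, int]:
    """Return (minority_label, majority_label); ties -> label 1 minority."""
    labels, counts = np.unique(y, return_counts=True)
    if labels.size != 2:
        raise ConfigurationError("oversampling expects exactly two classes")
    if counts[0] < counts[1]:
        return int(labels[0]), int(labels[1])
    if counts[1] < counts[0]:
        return int(labels[1]), int(labels[0])
    return int(labels[1]), int(labels[0])


def _zscore(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _minority_neighbor_graph(X_min_z: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest minority neighbours of each minority row,
    self excluded."""
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min_z)
    idx = nn.kneighbors(X_min_z, return_distance=False)
    return idx[:, 1:]


def _interpolate(
    X_min: np.ndarray,
    parents: np.ndarray,
    neighbor_graph: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    k = neighbor_graph.shape[1]
    picks = neighbor_graph[parents, rng.integers(0, k, size=parents.size)]
    u = rng.random((parents.size, 1))
    return X_min[parents] + u * (X_min[picks] - X_min[parents])


def _validate(X: np.ndarray, y: np.ndarray, config: OversamplerConfig, n_min: int) -> None:
    if n_min <= config.k_neighbors:
        raise ConfigurationError(
            f"minority class has {n_min} members; needs more than "
            f"k_neighbors={config.k_neighbors}"
        )


def smote(
    X: np.ndarray, y: np.ndarray, config: OversamplerConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform-parent minority interpolation until
    minority/majority = target_ratio.  Original rows are preserved."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    min_lab, maj_lab = _split_classes(y)
    min_idx = np.flatnonzero(y == min_lab)
    n_min, n_maj = min_idx.size, int(np.sum(y == maj_lab))
    n_new = int(round(config.target_ratio * n_maj)) - n_min
    if n_new <= 0:
        return X.copy(), y.copy()
    _validate(X, y, config, n_min)
    X_min = X[min_idx]
    graph = _minority_neighbor_graph(_zscore(X)[min_idx], config.k_neighbors)
    parents = rng.integers(0, n_min, size=n_new)
    X_new = _interpolate(X_min, parents, graph, rng)
    return (
        np.vstack([X, X_new]),
        np.concatenate([y, np.full(n_new, min_lab, dtype=int)]),
    )


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``; floors
    plus the largest fractional remainders, ties to the lower index."""
    quota = weights / weights.sum() * total
    alloc = np.floor(quota).astype(int)
    short = total - int(alloc.sum())
    if short > 0:
        remainders = quota - alloc
        order = np.lexsort((np.arange(weights.size), -remainders))
        alloc[order[:short]] += 1
    return alloc


def adasyn(
    X: np.ndarray, y: np.ndarray, config: OversamplerConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Boundary-weighted minority interpolation.

    Each minority point's weight r_i is the fraction of majority members
    among its k nearest neighbours over all classes; the synthetic budget
    G = (majority - minority) * target_ratio is allocated proportionally
    to the normalised r_i by largest-remainder rounding.  If no minority
    point touches the boundary (all r_i = 0) the allocation falls back to
    uniform, which makes the counts coincide with SMOTE's.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    min_lab, maj_lab = _split_classes(y)
    min_idx = np.flatnonzero(y == min_lab)
    n_min, n_maj = min_idx.size, int(np.sum(y == maj_lab))
    G = int(round((n_maj - n_min) * config.target_ratio))
    if G <= 0:
        return X.copy(), y.copy()
    _validate(X, y, config, n_min)

    Xz = _zscore(X)
    k = config.k_neighbors
    nn_all = NearestNeighbors(n_neighbors=k + 1).fit(Xz)
    nbrs = nn_all.kneighbors(Xz[min_idx], return_distance=False)[:, 1:]
    r = (y[nbrs] == maj_lab).sum(axis=1) / k
    if r.sum() == 0:
        logger.warning("ADASYN: no boundary minority points; falling back to uniform allocation")
        r = np.ones(n_min)
    alloc = _largest_remainder(r, G)

    X_min = X[min_idx]
    graph = _minority_neighbor_graph(Xz[min_idx], k)
    parents = np.repeat(np.arange(n_min), alloc)
    X_new = _interpolate(X_min, parents, graph, rng)
    return (
        np.vstack([X, X_new]),
        np.concatenate([y, np.full(G, min_lab, dtype=int)]),
    )


def oversample(
    X: np.ndarray, y: np.ndarray, config: OversamplerConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Dispatch on ``config.method``; ``"none"`` returns copies untouched."""
    if config.method == "none":
        return np.asarray(X, dtype=float).copy(), np.asarray(y, dtype=int).copy()
    if config.method == "smote":
        return smote(X, y, config, rng)
    return adasyn(X, y, config, rng)
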