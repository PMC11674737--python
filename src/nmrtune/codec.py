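"""Real-vector genome encoding of classifier configurations.

A genome is a fixed-length real vector.  Each coordinate is owned by a
*gene*: categorical genes map half-open unit intervals to labels
(``[0,1) -> first label, [1,2) -> second, ...``), integer genes are cast
by truncation over ``[lo, hi+1)`` so every integer gets equal measure,
and real genes pass through (log-scale genes are stored as log10 and
exponentiated on decode).  In 2-level mode the vector is extended by one
slot per dataset feature; slots in ``[0, 0.5)`` exclude the feature and
``[0.5, 1]`` include it.

Decoding is total on the bounds box, deterministic and piecewise
constant — perturbing a coordinate inside its bin never changes the
decoded configuration.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np

from ._exceptions import ConfigurationError, DecodeError, ShapeError
from .optim import Bounds

__all__ = [
    "ParamGene",
    "GenomeSchema",
    "DecodedConfig",
    "schema_bounds",
    "decode_categorical",
    "decode_integer",
    "decode_real",
    "decode_feature_mask",
    "decode",
    "preset_schema",
    "CLASSIFIER_IDS",
    "REGISTRY_VERSION",
    "default_registry",
    "load_registry",
    "save_registry",
]

REGISTRY_VERSION = "1.0"

CLASSIFIER_IDS = (
    "decision_tree",
    "extra_tree",
    "gradient_boosting",
    "knn",
    "lightgbm",
    "logistic_regression",
    "nusvm",
    "random_forest",
    "xgboost",
    "extra_trees",
)


@dataclass(frozen=True)
class ParamGene:
    """One hyperparameter dimension of the search space."""

    name: str
    kind: str  # "categorical" | "integer" | "real"
    categories: tuple = ()
    lo: float = 0.0
    hi: float = 1.0
    log_scale: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "integer", "real"):
            raise ConfigurationError(f"unknown gene kind {self.kind!r}")
        if self.kind == "categorical":
            if len(self.categories) < 2:
                raise ConfigurationError(
                    f"categorical gene {self.name!r} needs >= 2 categories"
                )
        else:
            if not self.lo < self.hi:
                raise ConfigurationError(
                    f"gene {self.name!r}: lo must be < hi ({self.lo} vs {self.hi})"
                )
            if self.kind == "integer" and (
                self.lo != int(self.lo) or self.hi != int(self.hi)
            ):
                raise ConfigurationError(
                    f"integer gene {self.name!r} needs integer lo/hi"
                )
            if self.log_scale and self.lo <= 0:
                raise ConfigurationError(
                    f"log-scale gene {self.name!r} needs lo > 0"
                )


@dataclass(frozen=True)
class GenomeSchema:
    """Ordered gene list plus an optional feature-mask segment."""

    genes: tuple[ParamGene, ...]
    n_features: int = 0
    classifier_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        if self.n_features < 0:
            raise ConfigurationError("n_features must be >= 0")

    @property
    def dim(self) -> int:
        return len(self.genes) + self.n_features


@dataclass
class DecodedConfig:
    """A genome decoded into named hyperparameters plus a feature mask."""

    params: dict[str, Any]
    feature_mask: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    @property
    def n_features_used(self) -> int:
        return int(self.feature_mask.sum()) if self.feature_mask.size else 0

    def cache_key(self) -> tuple:
        """Hashable identity; equal keys imply identical classifier behaviour."""
        return (
            tuple(sorted(self.params.items())),
            tuple(np.flatnonzero(self.feature_mask).tolist()),
        )


def schema_bounds(schema: GenomeSchema) -> Bounds:
    """Bounds box the optimizer searches for a given schema.

    Categorical genes get ``[0, K]`` (the top edge decodes to the last
    label by clamping), integer genes ``[lo, hi+1]`` so truncation can
    reach ``hi`` with equal measure, real genes their own range
    (log10-transformed for log-scale genes), mask slots ``[0, 1]``.
    """
    lower, upper = [], []
    for gene in schema.genes:
        if gene.kind == "categorical":
            lower.append(0.0)
            upper.append(float(len(gene.categories)))
        elif gene.kind == "integer":
            lower.append(float(gene.lo))
            upper.append(float(gene.hi) + 1.0)
        elif gene.log_scale:
            lower.append(math.log10(gene.lo))
            upper.append(math.log10(gene.hi))
        else:
            lower.append(float(gene.lo))
            upper.append(float(gene.hi))
    lower.extend([0.0] * schema.n_features)
    upper.extend([1.0] * schema.n_features)
    return Bounds(lower=np.array(lower), upper=np.array(upper))


def decode_categorical(value: float, categories: Sequence) -> Any:
    """Map a real in [0, K] to a label: index floor(value), clamped to K-1."""
    k = len(categories)
    if not 0.0 <= value <= k:
        raise DecodeError(f"categorical value {value} outside [0, {k}]")
    return categories[min(int(math.floor(value)), k - 1)]


def decode_integer(value: float, lo: int, hi: int) -> int:
    """Cast a real to an integer by truncation, clamped to [lo, hi]."""
    return int(min(max(math.floor(value), lo), hi))


def decode_real(value: float, log_scale: bool = False) -> float:
    return float(10.0 ** value) if log_scale else float(value)


def decode_feature_mask(values: np.ndarray) -> np.ndarray:
    """Threshold mask slots at 0.5; an all-excluded mask force-includes the
    slot with the maximum value so the decoded model always sees >= 1 feature."""
    values = np.asarray(values, dtype=float)
    mask = values >= 0.5
    if values.size and not mask.any():
        mask[int(np.argmax(values))] = True
    return mask


def decode(genome_values: np.ndarray, schema: GenomeSchema) -> DecodedConfig:
    """Decode a genome into a named hyperparameter assignment + feature mask."""
    genome_values = np.asarray(genome_values, dtype=float)
    if genome_values.shape != (schema.dim,):
        raise ShapeError(
            f"genome has shape {genome_values.shape}, schema dimension is {schema.dim}"
        )
    params: dict[str, Any] = {}
    for i, gene in enumerate(schema.genes):
        v = genome_values[i]
        if gene.kind == "categorical":
            params[gene.name] = decode_categorical(v, gene.categories)
        elif gene.kind == "integer":
            params[gene.name] = decode_integer(v, int(gene.lo), int(gene.hi))
        else:
            params[gene.name] = decode_real(v, gene.log_scale)
    mask = decode_feature_mask(genome_values[len(schema.genes):])
    return DecodedConfig(params=params, feature_mask=mask)


# ---------------------------------------------------------------------------
# Search-space registry
# ---------------------------------------------------------------------------
# Gene lists follow the published per-classifier parameter tables; numeric
# ranges are this package's versioned defaults and every entry can be
# overridden per run.  Category order is part of the format contract: the
# bin mapping depends on it.

def _cat(name, *categories):
    return {"name": name, "kind": "categorical", "categories": list(categories)}


def _int(name, lo, hi):
    return {"name": name, "kind": "integer", "lo": lo, "hi": hi}


def _real(name, lo, hi, log_scale=False):
    return {"name": name, "kind": "real", "lo": lo, "hi": hi, "log_scale": log_scale}


_TREE_GENES = [
    _cat("criterion", "gini", "entropy", "log_loss"),
    _cat("splitter", "best", "random"),
    _int("max_depth", 2, 20),
    _int("min_samples_split", 2, 20),
    _int("min_samples_leaf", 1, 20),
    _real("min_weight_fraction_leaf", 0.0, 0.1),
    _int("max_leaf_nodes", 8, 256),
    _real("min_impurity_decrease", 0.0, 0.02),
    _real("ccp_alpha", 0.0, 0.02),
]

_FOREST_GENES = [
    _cat("criterion", "gini", "entropy", "log_loss"),
    _int("n_estimators", 50, 300),
    _int("max_depth", 4, 20),
    _int("min_samples_split", 2, 20),
    _int("min_samples_leaf", 1, 10),
    _real("min_weight_fraction_leaf", 0.0, 0.05),
    _int("max_leaf_nodes", 16, 256),
    _real("min_impurity_decrease", 0.0, 0.01),
    _real("ccp_alpha", 0.0, 0.01),
    _cat("bootstrap", True, False),
    _real("max_samples", 0.5, 1.0),
]

DEFAULT_REGISTRY: dict[str, list[dict]] = {
    "decision_tree": copy.deepcopy(_TREE_GENES),
    "extra_tree": copy.deepcopy(_TREE_GENES),
    "gradient_boosting": [
        _int("n_estimators", 50, 300),
        _int("max_depth", 2, 10),
        _cat("loss", "log_loss", "exponential"),
        _real("learning_rate", 1e-3, 0.3, log_scale=True),
        _cat("criterion", "friedman_mse", "squared_error"),
        _real("subsample", 0.5, 1.0),
        _int("min_samples_split", 2, 20),
        _int("min_samples_leaf", 1, 10),
        _real("min_weight_fraction_leaf", 0.0, 0.05),
        _real("min_impurity_decrease", 0.0, 0.01),
        _int("max_leaf_nodes", 8, 256),
        _real("ccp_alpha", 0.0, 0.01),
    ],
    "knn": [
        _cat("metric", "euclidean", "manhattan", "chebyshev"),
        _cat("weights", "uniform", "distance"),
        _int("n_neighbors", 1, 10),
    ],
    "lightgbm": [
        _int("n_estimators", 50, 300),
        _int("max_depth", 2, 15),
        _real("min_child_weight", 1e-3, 10.0, log_scale=True),
        _real("learning_rate", 1e-3, 0.3, log_scale=True),
        _real("gamma", 0.0, 5.0),
        _real("subsample", 0.5, 1.0),
        _real("colsample_bytree", 0.5, 1.0),
        _real("reg_alpha", 1e-3, 10.0, log_scale=True),
        _real("reg_lambda", 1e-3, 10.0, log_scale=True),
        _cat("eval_metric", "binary_logloss", "auc"),
        _int("num_leaves", 4, 128),
        _int("min_child_samples", 2, 50),
        _int("bagging_freq", 0, 10),
        _real("feature_fraction", 0.5, 1.0),
        _real("bagging_fraction", 0.5, 1.0),
    ],
    "logistic_regression": [
        _real("C", 1e-3, 1e3, log_scale=True),
        _int("max_iter", 50, 500),
        _cat("penalty", "l1", "l2", "elasticnet"),
        _cat("dual", False, True),
        _cat("fit_intercept", True, False),
        _cat("solver", "lbfgs", "liblinear", "saga"),
        _real("l1_ratio", 0.0, 1.0),
    ],
    "nusvm": [
        _cat("kernel", "linear", "poly", "rbf", "sigmoid"),
        _real("nu", 0.05, 0.9),
        _int("degree", 2, 5),
        _real("gamma", 1e-4, 10.0, log_scale=True),
    ],
    "random_forest": copy.deepcopy(_FOREST_GENES),
    "xgboost": [
        _int("n_estimators", 50, 300),
        _int("max_depth", 2, 15),
        _real("min_child_weight", 1e-3, 10.0, log_scale=True),
        _real("learning_rate", 1e-3, 0.3, log_scale=True),
        _real("gamma", 0.0, 5.0),
        _real("subsample", 0.5, 1.0),
        _real("colsample_bytree", 0.5, 1.0),
        _real("reg_alpha", 1e-3, 10.0, log_scale=True),
        _real("reg_lambda", 1e-3, 10.0, log_scale=True),
    ],
    "extra_trees": copy.deepcopy(_FOREST_GENES),
}


def default_registry() -> dict:
    """Deep copy of the built-in search-space registry."""
    return copy.deepcopy(DEFAULT_REGISTRY)


def save_registry(registry: Mapping[str, list[dict]], path: str | Path) -> None:
    payload = {"version": REGISTRY_VERSION, "classifiers": dict(registry)}
    Path(path).write_text(json.dumps(payload, indent=2))


def load_registry(path: str | Path) -> dict:
    payload = json.loads(Path(path).read_text())
    return payload["classifiers"]


def _gene_from_dict(d: Mapping) -> ParamGene:
    return ParamGene(
        name=d["name"],
        kind=d["kind"],
        categories=tuple(d.get("categories", ())),
        lo=d.get("lo", 0.0),
        hi=d.get("hi", 1.0),
        log_scale=bool(d.get("log_scale", False)),
    )


def preset_schema(
    classifier_id: str,
    n_features: int = 0,
    mode: str = "1level",
    registry: Mapping[str, list[dict]] | None = None,
    overrides: Mapping[str, Mapping] | None = None,
) -> GenomeSchema:
    """Schema for one of the ten supported classifiers.

    ``mode="2level"`` appends ``n_features`` feature-mask slots.
    ``overrides`` patches individual gene fields by name, e.g.
    ``{"n_estimators": {"lo": 20, "hi": 60}}``.
    """
    if classifier_id not in CLASSIFIER_IDS:
        raise ConfigurationError(
            f"unknown classifier {classifier_id!r}; expected one of {CLASSIFIER_IDS}"
        )
    if mode not in ("1level", "2level"):
        raise ConfigurationError(f"mode must be '1level' or '2level', got {mode!r}")
    if mode == "2level" and n_features < 1:
        raise ConfigurationError("2level mode requires n_features >= 1")
    source = registry if registry is not None else DEFAULT_REGISTRY
    gene_dicts = copy.deepcopy(list(source[classifier_id]))
    if overrides:
        by_name = {g["name"]: g for g in gene_dicts}
        for name, patch in overrides.items():
            if name not in by_name:
                raise ConfigurationError(
                    f"override target {name!r} not a gene of {classifier_id!r}"
                )
            by_name[name].update(patch)
    genes = tuple(_gene_from_dict(g) for g in gene_dicts)
    return GenomeSchema(
        genes=genes,
        n_features=n_features if mode == "2level" else 0,
        classifier_id=classifier_id,
    )
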