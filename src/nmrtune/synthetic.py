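"""Synthetic thyroid-nodule-like tabular data and optimizer benchmarks.

The default generator emulates the schema of the Shengjing Hospital
thyroid-nodule cohort: 18 predictors mixing patient age, binary
ultrasound findings (multifocality, irregular shape, unclear margin,
calcification, ...), small-cardinality categoricals (nodule site, echo
strength, composition) and positively skewed laboratory values
(TSH, TPO, TGAb), with a malignant:benign prevalence near 819:413
(0.6648).  Labels come from a logistic model over a configurable set of
relevant features with the intercept calibrated by bisection to hit the
target prevalence; all other features are independent of the label, so
planted relevance is known exactly and feature-selection recovery can be
scored.

The module also provides standard continuous benchmark functions
(sphere, Rastrigin, Rosenbrock) as maximization targets for exercising
the optimizer without any classifier in the loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from ._exceptions import CalibrationError, ConfigurationError
from .evaluation import TabularDataset
from .optim import Bounds

__all__ = [
    "FeatureSpec",
    "SyntheticSpec",
    "thyroid_schema",
    "generate_tabular",
    "BenchmarkProblem",
    "benchmark_function",
    "planted_recovery_fixture",
]


@dataclass(frozen=True)
class FeatureSpec:
    """One synthetic feature: name, distribution family and its parameters.

    kinds: ``binary`` (Bernoulli(p)), ``categorical`` (uniform over K),
    ``continuous`` (uniform on [lo, hi]), ``positive_skewed``
    (log-normal(mu, sigma) — heavy right tail as seen in antibody titres).
    """

    name: str
    kind: str
    p: float = 0.5  # binary
    k: int = 2  # categorical
    lo: float = 0.0  # continuous
    hi: float = 1.0
    mu: float = 0.0  # positive_skewed (log-space)
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "categorical", "continuous", "positive_skewed"):
            raise ConfigurationError(f"unknown feature kind {self.kind!r}")


def thyroid_schema() -> tuple[FeatureSpec, ...]:
    """The 18-predictor schema the generator emulates, with marginal
    parameters chosen to resemble the cohort's summary statistics."""
    return (
        FeatureSpec("Age", "continuous", lo=20.0, hi=75.0),
        FeatureSpec("Gender", "binary", p=0.84),
        FeatureSpec("FT3", "continuous", lo=2.0, hi=7.0),
        FeatureSpec("FT4", "continuous", lo=9.0, hi=22.0),
        FeatureSpec("TSH", "positive_skewed", mu=0.38, sigma=1.0),
        FeatureSpec("TPO", "positive_skewed", mu=-0.47, sigma=2.2),
        FeatureSpec("TGAb", "positive_skewed", mu=0.99, sigma=2.0),
        FeatureSpec("Site", "categorical", k=3),
        FeatureSpec("Echo_pattern", "binary", p=0.11),
        FeatureSpec("Multifocality", "binary", p=0.46),
        FeatureSpec("Size", "positive_skewed", mu=0.26, sigma=0.55),
        FeatureSpec("Shape", "binary", p=0.21),
        FeatureSpec("Margin", "binary", p=0.67),
        FeatureSpec("Calcification", "binary", p=0.40),
        FeatureSpec("Echo_strength", "categorical", k=5),
        FeatureSpec("Blood_flow", "binary", p=0.36),
        FeatureSpec("Composition", "categorical", k=3),
        FeatureSpec("Multilateral", "binary", p=0.77),
    )


#: Default planted signal: ultrasound findings clinicians weight most,
#: with log-odds effects on the z-scored feature.
DEFAULT_EFFECTS: dict[str, float] = {
    "Calcification": 1.3,
    "Multilateral": 1.1,
    "Shape": 1.0,
    "Margin": 0.8,
    "Composition": 0.6,
}


@dataclass
class SyntheticSpec:
    n: int = 1232
    schema: tuple[FeatureSpec, ...] = field(default_factory=thyroid_schema)
    effect_sizes: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    prevalence: float = 819 / 1232  # 0.6648 malignant fraction
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        names = {f.name for f in self.schema}
        unknown = set(self.effect_sizes) - names
        if unknown:
            raise ConfigurationError(f"effect sizes name unknown features: {sorted(unknown)}")
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigurationError("prevalence must be in (0, 1)")


def _draw_feature(spec: FeatureSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    if spec.kind == "binary":
        return (rng.random(n) < spec.p).astype(float)
    if spec.kind == "categorical":
        return rng.integers(0, spec.k, size=n).astype(float)
    if spec.kind == "continuous":
        return rng.uniform(spec.lo, spec.hi, size=n)
    return rng.lognormal(spec.mu, spec.sigma, size=n)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _calibrate_intercept(linear: np.ndarray, prevalence: float, tol: float = 1e-6) -> float:
    """Bisection on the intercept so mean sigmoid(intercept + linear)
    equals the target prevalence."""
    lo, hi = -40.0, 40.0
    mean_p = lambda c: float(np.mean(_sigmoid(c + linear)))
    if not mean_p(lo) <= prevalence <= mean_p(hi):
        raise CalibrationError(f"prevalence {prevalence} unreachable by intercept shift")
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if mean_p(mid) < prevalence:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return (lo + hi) / 2.0


def generate_tabular(spec: SyntheticSpec) -> TabularDataset:
    """Draw a dataset from the spec; bit-identical for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    columns = {f.name: _draw_feature(f, spec.n, rng) for f in spec.schema}
    X = np.column_stack([columns[f.name] for f in spec.schema])

    linear = np.zeros(spec.n)
    for name, beta in spec.effect_sizes.items():
        col = columns[name]
        sd = col.std()
        z = (col - col.mean()) / (sd if sd > 0 else 1.0)
        linear += beta * z
    if spec.noise_sd > 0:
        linear += rng.normal(0.0, spec.noise_sd, size=spec.n)

    intercept = _calibrate_intercept(linear, spec.prevalence)
    y = (rng.random(spec.n) < _sigmoid(intercept + linear)).astype(int)
    # degenerate draws (tiny n) could miss a class; regenerate labels from
    # fresh uniforms rather than fail validation
    while np.unique(y).size < 2:
        y = (rng.random(spec.n) < _sigmoid(intercept + linear)).astype(int)

    return TabularDataset(
        X=X,
        y=y,
        feature_names=tuple(f.name for f in spec.schema),
        label_name="Mal",
    )


@dataclass(frozen=True)
class BenchmarkProblem:
    """A maximization target with known optimum for optimizer tests."""

    name: str
    fitness: Callable[[np.ndarray], float]
    bounds: Bounds
    optimum_location: np.ndarray
    optimum_value: float = 0.0


def benchmark_function(name: str, dim: int) -> BenchmarkProblem:
    """Standard continuous benchmarks, negated so the optimum value is 0
    and the optimizer maximizes."""
    if dim < 1:
        raise ConfigurationError("dim must be >= 1")
    if name == "sphere":
        fit = lambda x: -float(np.sum(np.asarray(x) ** 2))
        box, opt = 5.12, np.zeros(dim)
    elif name == "rastrigin":
        fit = lambda x: -float(
            10.0 * dim
            + np.sum(np.asarray(x) ** 2 - 10.0 * np.cos(2.0 * np.pi * np.asarray(x)))
        )
        box, opt = 5.12, np.zeros(dim)
    elif name == "rosenbrock":
        def fit(x, _d=dim):
            x = np.asarray(x, dtype=float)
            if _d == 1:
                return -float((1.0 - x[0]) ** 2)
            return -float(
                np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2)
            )
        box, opt = 5.0, np.ones(dim)
    else:
        raise ConfigurationError(f"unknown benchmark {name!r}")
    bounds = Bounds(lower=np.full(dim, -box), upper=np.full(dim, box))
    return BenchmarkProblem(
        name=name, fitness=fit, bounds=bounds, optimum_location=opt, optimum_value=0.0
    )


def planted_recovery_fixture(
    p: int = 18,
    n_relevant: int = 5,
    n: int = 1000,
    seed: int = 0,
    effect: float = 2.0,
    prevalence: float = 0.5,
) -> tuple[TabularDataset, np.ndarray]:
    """Gaussian-feature dataset where exactly ``n_relevant`` features carry
    a strong logistic signal; returns the ground-truth relevance mask."""
    if n_relevant > p:
        raise ConfigurationError("n_relevant must be <= p")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    relevant = rng.choice(p, size=n_relevant, replace=False) if n_relevant else np.array([], dtype=int)
    mask = np.zeros(p, dtype=bool)
    mask[relevant] = True
    linear = X[:, relevant].sum(axis=1) * effect if n_relevant else np.zeros(n)
    intercept = _calibrate_intercept(linear, prevalence)
    y = (rng.random(n) < _sigmoid(intercept + linear)).astype(int)
    while np.unique(y).size < 2:
        y = (rng.random(n) < _sigmoid(intercept + linear)).astype(int)
    dataset = TabularDataset(
        X=X,
        y=y,
        feature_names=tuple(f"f{i}" for i in range(p)),
        label_name="label",
    )
    return dataset, mask
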