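"""Naked mole-rat (NMR) population metaheuristic.

The algorithm maintains a population of real-valued genomes split each
generation into *breeders* (the fittest fraction) and *workers*.  Breeders
exploit: with probability ``pb`` they move toward the global best along a
per-dimension convex combination, otherwise they take a heavy-tailed Lévy
step away from it (exploration).  Workers explore via differential moves
built from two random population members.  Candidates are then optionally
recombined with the global best (uniform crossover) and mutated gene-wise,
clamped to the bounds, and accepted only if strictly fitter (greedy,
elitist selection).  Fitness is always **maximized**.

Determinism contract: every candidate draws from an RNG stream keyed by
``(seed, epoch, slot)``, so results are bit-identical for a fixed seed
regardless of how many parallel workers evaluate fitness.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from joblib import Parallel, delayed

from ._exceptions import BoundsError, ConfigurationError

logger = logging.getLogger("nmrtune.optim")

__all__ = [
    "NMRConfig",
    "Bounds",
    "Genome",
    "OptimizationResult",
    "levy_step",
    "crossover",
    "mutate",
    "worker_update",
    "breeder_update",
    "initialize_population",
    "optimize",
    "random_search",
]

#: Fitness assigned to candidates whose evaluation failed or was non-finite.
SENTINEL_WORST = -math.inf


@dataclass(frozen=True)
class NMRConfig:
    """Run parameters of the naked mole-rat optimizer.

    Defaults for ``pb`` and ``pm`` follow the published configuration
    (breeding probability 0.75, per-gene mutation probability 0.1).  The
    full-scale study budget is ``pop_size=1000, epochs=200``; desk-scale
    runs use far smaller budgets.
    """

    pop_size: int = 1000
    epochs: int = 200
    pb: float = 0.75
    pm: float = 0.1
    breeder_fraction: float = 0.2
    levy_beta: float = 1.5
    levy_scale: float | None = None  # None -> 0.01 * per-dimension range
    crossover_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 4:
            raise ConfigurationError(f"pop_size must be >= 4, got {self.pop_size}")
        if self.epochs < 0:
            raise ConfigurationError(f"epochs must be >= 0, got {self.epochs}")
        for name in ("pb", "pm", "crossover_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.breeder_fraction < 1.0:
            raise ConfigurationError(
                f"breeder_fraction must be in (0, 1), got {self.breeder_fraction}"
            )
        if not 1.0 < self.levy_beta <= 2.0:
            raise ConfigurationError(
                f"levy_beta must be in (1, 2], got {self.levy_beta}"
            )
        if self.levy_scale is not None and self.levy_scale <= 0:
            raise ConfigurationError(
                f"levy_scale must be positive, got {self.levy_scale}"
            )


@dataclass(frozen=True)
class Bounds:
    """Per-dimension box constraints; ``lower[d] < upper[d]`` for all d."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if lower.ndim != 1 or lower.shape != upper.shape:
            raise BoundsError("lower and upper must be 1-D arrays of equal length")
        if lower.size == 0:
            raise BoundsError("bounds must have at least one dimension")
        if not np.all(lower < upper):
            bad = np.flatnonzero(~(lower < upper))
            raise BoundsError(f"lower must be < upper in every dimension; bad: {bad.tolist()}")

    @property
    def dim(self) -> int:
        return self.lower.size

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def clamp(self, values: np.ndarray) -> np.ndarray:
        return np.clip(values, self.lower, self.upper)


@dataclass
class Genome:
    """One candidate solution: a bounded real vector plus its fitness.

    ``fitness is None`` marks an unevaluated genome.
    """

    values: np.ndarray
    fitness: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class OptimizationResult:
    best_genome: Genome
    best_fitness: float
    history: np.ndarray  # best-so-far fitness, entry 0 = after initialization
    evaluations: int
    config: NMRConfig | None = field(default=None, repr=False)


def _mantegna_sigma(beta: float) -> float:
    """Scale of the numerator Gaussian in the Mantegna Lévy generator."""
    num = math.gamma(1.0 + beta) * math.sin(math.pi * beta / 2.0)
    den = math.gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0)
    return (num / den) ** (1.0 / beta)


def levy_step(beta: float, rng: np.random.Generator, size: int | tuple | None = None):
    """Heavy-tailed Lévy step(s) via the Mantegna construction u / |v|^(1/beta)."""
    if not 1.0 < beta <= 2.0:
        raise ConfigurationError(f"levy beta must be in (1, 2], got {beta}")
    sigma = _mantegna_sigma(beta)
    u = rng.normal(0.0, sigma, size=size)
    v = rng.normal(0.0, 1.0, size=size)
    return u / np.abs(v) ** (1.0 / beta)


def crossover(a: np.ndarray, b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniform crossover: each gene taken from ``a`` or ``b`` with probability 1/2."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        from ._exceptions import ShapeError

        raise ShapeError(f"parent shapes differ: {a.shape} vs {b.shape}")
    take_a = rng.random(a.shape) < 0.5
    return np.where(take_a, a, b)


def mutate(values: np.ndarray, pm: float, bounds: Bounds, rng: np.random.Generator) -> np.ndarray:
    """Each gene independently, with probability ``pm``, resampled uniformly in its bounds."""
    if not 0.0 <= pm <= 1.0:
        raise ConfigurationError(f"pm must be in [0, 1], got {pm}")
    values = np.asarray(values, dtype=float)
    hit = rng.random(values.shape) < pm
    fresh = rng.uniform(bounds.lower, bounds.upper)
    return np.where(hit, fresh, values)


def worker_update(
    worker_index: int,
    population: np.ndarray,
    bounds: Bounds,
    rng: np.random.Generator,
) -> np.ndarray:
    """Differential worker move: w' = w + lambda * (x_j - x_k).

    ``x_j, x_k`` are two distinct population members different from the
    worker; ``lambda ~ U(0,1)`` is drawn per dimension.  The candidate is
    clamped to the bounds; greedy acceptance happens in :func:`optimize`.
    """
    n = population.shape[0]
    if n < 3:
        raise ConfigurationError("worker update needs a population of at least 3")
    others = [i for i in range(n) if i != worker_index]
    j, k = rng.choice(others, size=2, replace=False)
    lam = rng.random(population.shape[1])
    candidate = population[worker_index] + lam * (population[j] - population[k])
    return bounds.clamp(candidate)


def breeder_update(
    breeder: np.ndarray,
    best: np.ndarray,
    config: NMRConfig,
    bounds: Bounds,
    rng: np.random.Generator,
) -> np.ndarray:
    """Breeder move: exploit toward the best or take a Lévy excursion.

    With probability ``pb`` the candidate is the per-dimension convex
    combination ``b' = (1 - lam) * b + lam * best``; otherwise it steps
    ``b' = b + levy_scale * L * (b - best)`` with ``L`` a Lévy(beta) draw
    per dimension — the heavy tail grants occasional long jumps out of the
    exploitation basin.
    """
    breeder = np.asarray(breeder, dtype=float)
    best = np.asarray(best, dtype=float)
    if rng.random() < config.pb:
        lam = rng.random(breeder.shape)
        candidate = (1.0 - lam) * breeder + lam * best
    else:
        scale = (
            config.levy_scale
            if config.levy_scale is not None
            else 0.01 * bounds.width
        )
        steps = levy_step(config.levy_beta, rng, size=breeder.shape)
        candidate = breeder + scale * steps * (breeder - best)
    return bounds.clamp(candidate)


def initialize_population(bounds: Bounds, config: NMRConfig) -> list[Genome]:
    """Uniform initial population; reproducible from ``config.seed``."""
    rng = np.random.default_rng([config.seed, 0])
    values = rng.uniform(bounds.lower, bounds.upper, size=(config.pop_size, bounds.dim))
    return [Genome(values=row) for row in values]


def _safe_fitness(fitness: Callable[[np.ndarray], float], values: np.ndarray) -> float:
    """Evaluate one candidate, mapping failures to the sentinel-worst score."""
    from ._exceptions import EvaluationFailed

    try:
        score = float(fitness(values))
    except EvaluationFailed as exc:
        logger.warning("evaluation failed, assigning sentinel fitness: %s", exc)
        return SENTINEL_WORST
    if not math.isfinite(score):
        logger.warning("non-finite fitness %r, assigning sentinel fitness", score)
        return SENTINEL_WORST
    return score


def _evaluate_many(
    fitness: Callable[[np.ndarray], float],
    candidates: Sequence[np.ndarray],
    n_jobs: int,
) -> list[float]:
    if n_jobs == 1:
        return [_safe_fitness(fitness, c) for c in candidates]
    return Parallel(n_jobs=n_jobs)(
        delayed(_safe_fitness)(fitness, c) for c in candidates
    )


def optimize(
    fitness: Callable[[np.ndarray], float],
    bounds: Bounds,
    config: NMRConfig,
    n_jobs: int = 1,
) -> OptimizationResult:
    """Run the NMR metaheuristic, maximizing ``fitness`` over the bounds box.

    ``fitness`` must be deterministic given a genome (cross-validated
    fitness achieves this by fixing the fold plan per run).  Candidates
    raising :class:`~nmrtune._exceptions.EvaluationFailed` or returning
    non-finite values receive a sentinel-worst score and are logged, never
    raised.  Returns the best-ever genome, the monotone best-so-far
    history (entry 0 after initialization) and the exact evaluation count.
    """
    pop = initialize_population(bounds, config)
    values = np.stack([g.values for g in pop])
    fits = np.array(_evaluate_many(fitness, list(values), n_jobs))
    evaluations = config.pop_size

    # stable sort, descending fitness; ties keep earlier index
    order = np.argsort(-fits, kind="stable")
    values, fits = values[order], fits[order]

    best_values = values[0].copy()
    best_fitness = float(fits[0])
    history = [best_fitness]
    n_breeders = max(1, math.ceil(config.breeder_fraction * config.pop_size))

    for epoch in range(1, config.epochs + 1):
        candidates = []
        for slot in range(config.pop_size):
            rng = np.random.default_rng([config.seed, epoch, slot])
            if slot < n_breeders:
                cand = breeder_update(values[slot], best_values, config, bounds, rng)
            else:
                cand = worker_update(slot, values, bounds, rng)
            if rng.random() < config.crossover_prob:
                cand = crossover(cand, best_values, rng)
            cand = mutate(cand, config.pm, bounds, rng)
            candidates.append(bounds.clamp(cand))

        cand_fits = _evaluate_many(fitness, candidates, n_jobs)
        evaluations += config.pop_size
        for slot, (cand, cf) in enumerate(zip(candidates, cand_fits)):
            if cf > fits[slot]:  # strict: ties keep the incumbent
                values[slot] = cand
                fits[slot] = cf

        order = np.argsort(-fits, kind="stable")
        values, fits = values[order], fits[order]
        if fits[0] > best_fitness:
            best_fitness = float(fits[0])
            best_values = values[0].copy()
        history.append(best_fitness)

    return OptimizationResult(
        best_genome=Genome(values=best_values, fitness=best_fitness),
        best_fitness=best_fitness,
        history=np.array(history),
        evaluations=evaluations,
        config=config,
    )


def random_search(
    fitness: Callable[[np.ndarray], float],
    bounds: Bounds,
    n_evaluations: int,
    seed: int = 0,
) -> OptimizationResult:
    """Uniform random search at a fixed evaluation budget (baseline)."""
    rng = np.random.default_rng(seed)
    best_values, best_fitness = None, SENTINEL_WORST
    history = []
    for _ in range(n_evaluations):
        cand = rng.uniform(bounds.lower, bounds.upper)
        score = _safe_fitness(fitness, cand)
        if score > best_fitness:
            best_fitness, best_values = score, cand
        history.append(best_fitness)
    return OptimizationResult(
        best_genome=Genome(values=best_values, fitness=best_fitness),
        best_fitness=best_fitness,
        history=np.array(history),
        evaluations=n_evaluations,
    )
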