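"""Unit and property tests for the naked mole-rat optimizer primitives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmrtune import (
    Bounds,
    NMRConfig,
    benchmark_function,
    crossover,
    levy_step,
    mutate,
    optimize,
    random_search,
)
from nmrtune._exceptions import BoundsError, ConfigurationError, EvaluationFailed, ShapeError
from nmrtune.optim import breeder_update, initialize_population, worker_update


def unit_bounds(d):
    return Bounds(lower=np.zeros(d), upper=np.ones(d))


class TestConfigAndBounds:
    def test_config_validation(self):
        with pytest.raises(ConfigurationError):
            NMRConfig(pop_size=3)
        with pytest.raises(ConfigurationError):
            NMRConfig(pb=1.5)
        with pytest.raises(ConfigurationError):
            NMRConfig(levy_beta=1.0)
        with pytest.raises(ConfigurationError):
            NMRConfig(breeder_fraction=0.0)

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(BoundsError):
            Bounds(lower=np.array([0.0, 1.0]), upper=np.array([1.0, 1.0]))


class TestInitialization:
    def test_reproducible_and_in_bounds(self):
        bounds = unit_bounds(2)
        cfg = NMRConfig(pop_size=4, epochs=1, seed=11)
        pop1 = initialize_population(bounds, cfg)
        pop2 = initialize_population(bounds, cfg)
        assert len(pop1) == 4
        for g1, g2 in zip(pop1, pop2):
            assert np.array_equal(g1.values, g2.values)
            assert np.all((g1.values >= 0) & (g1.values <= 1))
            assert g1.fitness is None

    def test_uniform_sampling_mean(self):
        # CLT: mean of 1000 U(-5,5) draws within 3 * (10/sqrt(12)) / sqrt(1000)
        bounds = Bounds(lower=np.array([-5.0]), upper=np.array([5.0]))
        pop = initialize_population(bounds, NMRConfig(pop_size=1000, epochs=1, seed=3))
        mean = np.mean([g.values[0] for g in pop])
        assert abs(mean) < 3 * (10 / math.sqrt(12)) / math.sqrt(1000)


class TestWorkerUpdate:
    def test_identical_population_is_fixed_point(self, rng):
        pop = np.tile([0.4, 0.6], (5, 1))
        cand = worker_update(2, pop, unit_bounds(2), rng)
        assert np.allclose(cand, pop[2])

    def test_candidate_clamped(self, rng):
        pop = np.array([[0.99, 0.99], [0.0, 0.0], [0.98, 0.98], [0.5, 0.5]])
        for _ in range(50):
            cand = worker_update(0, pop, unit_bounds(2), rng)
            assert np.all(cand <= 1.0) and np.all(cand >= 0.0)

    def test_small_population_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            worker_update(0, np.zeros((2, 3)), unit_bounds(3), rng)


class TestBreederUpdate:
    def test_breeder_equal_best_is_fixed_point(self, rng):
        # both branches: convex combination of b with itself, and a Lévy
        # step along the zero direction b - best
        best = np.array([0.3, 0.7])
        for pb in (0.0, 1.0):
            cfg = NMRConfig(pop_size=4, epochs=1, pb=pb)
            cand = breeder_update(best.copy(), best, cfg, unit_bounds(2), rng)
            assert np.allclose(cand, best)

    def test_convex_combination_stays_between(self, rng):
        cfg = NMRConfig(pop_size=4, epochs=1, pb=1.0)
        b, best = np.array([0.1, 0.9]), np.array([0.8, 0.2])
        for _ in range(50):
            cand = breeder_update(b, best, cfg, unit_bounds(2), rng)
            assert np.all(cand >= np.minimum(b, best) - 1e-12)
            assert np.all(cand <= np.maximum(b, best) + 1e-12)

    def test_levy_branch_has_heavier_tail_than_gaussian(self):
        # Mantegna generator at beta=1.5: P(|L| > 3*sigma_hat) must exceed
        # the Gaussian tail mass 0.0027
        draws = levy_step(1.5, np.random.default_rng(1), size=100_000)
        tail = np.mean(np.abs(draws) > 3 * draws.std())
        assert tail > 0.0027


class TestLevyStep:
    def test_invalid_beta(self, rng):
        for beta in (0.5, 1.0, 2.5):
            with pytest.raises(ConfigurationError):
                levy_step(beta, rng)

    def test_seeded_reproducibility(self):
        a = levy_step(1.5, np.random.default_rng(5), size=100)
        b = levy_step(1.5, np.random.default_rng(5), size=100)
        assert np.array_equal(a, b)

    def test_beta_two_gaussian_limit_finite_variance(self):
        draws = levy_step(2.0, np.random.default_rng(2), size=100_000)
        assert np.isfinite(draws.var())
        assert draws.var() < 10

    def test_tail_index_matches_beta(self):
        # Hill estimator on the top order statistics of |draws| should
        # recover the stability exponent 1.5 within [1.3, 1.7]
        draws = np.abs(levy_step(1.5, np.random.default_rng(0), size=1_000_000))
        top = np.sort(draws)[::-1][:2000]
        hill = 1.0 / np.mean(np.log(top[:-1]) - np.log(top[-1]))
        assert 1.3 <= hill <= 1.7


class TestCrossoverMutate:
    def test_crossover_identical_parents(self, rng):
        a = np.array([1.0, 2.0, 3.0])
        assert np.array_equal(crossover(a, a.copy(), rng), a)

    def test_crossover_shape_mismatch(self, rng):
        with pytest.raises(ShapeError):
            crossover(np.zeros(3), np.zeros(4), rng)

    def test_crossover_inheritance_is_balanced(self):
        # 1e4 single-gene children: fraction from parent a in 0.5 +/- 0.015
        rng = np.random.default_rng(0)
        a, b = np.array([0.0]), np.array([1.0])
        children = np.array([crossover(a, b, rng)[0] for _ in range(10_000)])
        frac_a = np.mean(children == 0.0)
        assert abs(frac_a - 0.5) < 0.015

    def test_mutate_pm_zero_identity(self, rng):
        g = np.array([0.2, 0.8])
        assert np.array_equal(mutate(g, 0.0, unit_bounds(2), rng), g)

    def test_mutate_pm_one_resamples_in_bounds(self, rng):
        g = np.full(50, 0.5)
        out = mutate(g, 1.0, unit_bounds(50), rng)
        assert np.all((out >= 0) & (out <= 1))
        assert not np.array_equal(out, g)

    def test_mutate_hit_rate_binomial_mean(self):
        # D=100, pm=0.1 over 3000 trials: mean mutated count within 10 +/- 0.9
        rng = np.random.default_rng(7)
        bounds = unit_bounds(100)
        g = np.full(100, 0.5)
        counts = [np.sum(mutate(g, 0.1, bounds, rng) != 0.5) for _ in range(3000)]
        assert abs(np.mean(counts) - 10.0) < 0.9


class TestOptimize:
    def test_sphere_convergence_and_budget(self):
        prob = benchmark_function("sphere", 5)
        cfg = NMRConfig(pop_size=30, epochs=100, seed=1)
        res = optimize(prob.fitness, prob.bounds, cfg)
        assert res.best_fitness > -1e-2
        assert res.evaluations == 30 * 101
        assert res.evaluations <= cfg.pop_size * (cfg.epochs + 1) * 2

    def test_history_monotone_and_matches_best(self):
        prob = benchmark_function("rastrigin", 3)
        res = optimize(prob.fitness, prob.bounds, NMRConfig(pop_size=10, epochs=30, seed=4))
        assert np.all(np.diff(res.history) >= 0)
        assert res.best_fitness == res.history[-1]
        assert prob.fitness(res.best_genome.values) == res.best_fitness

    def test_zero_epochs_returns_initial_best(self):
        prob = benchmark_function("sphere", 3)
        cfg = NMRConfig(pop_size=10, epochs=0, seed=2)
        res = optimize(prob.fitness, prob.bounds, cfg)
        init_best = max(prob.fitness(g.values) for g in initialize_population(prob.bounds, cfg))
        assert res.best_fitness == init_best

    def test_seed_determinism_across_thread_counts(self):
        prob = benchmark_function("sphere", 4)
        cfg = NMRConfig(pop_size=10, epochs=10, seed=9)
        r1 = optimize(prob.fitness, prob.bounds, cfg, n_jobs=1)
        r2 = optimize(prob.fitness, prob.bounds, cfg, n_jobs=2)
        assert np.array_equal(r1.best_genome.values, r2.best_genome.values)
        assert np.array_equal(r1.history, r2.history)

    def test_bounds_respected_by_best(self):
        prob = benchmark_function("rosenbrock", 4)
        res = optimize(prob.fitness, prob.bounds, NMRConfig(pop_size=12, epochs=20, seed=0))
        assert np.all(res.best_genome.values >= prob.bounds.lower)
        assert np.all(res.best_genome.values <= prob.bounds.upper)

    def test_failing_and_nonfinite_fitness_get_sentinel(self):
        bounds = unit_bounds(2)

        def flaky(x):
            if x[0] < 0.3:
                raise EvaluationFailed("backend rejected")
            if x[0] < 0.5:
                return float("nan")
            return -x[1]

        res = optimize(flaky, bounds, NMRConfig(pop_size=10, epochs=10, seed=0))
        assert math.isfinite(res.best_fitness)
        assert res.best_genome.values[0] >= 0.5

    def test_beats_random_search_on_quadratic(self):
        # median final error over paired seeds must be strictly better
        prob = benchmark_function("sphere", 5)
        nmr, rnd = [], []
        for s in range(5):
            r1 = optimize(prob.fitness, prob.bounds, NMRConfig(pop_size=20, epochs=50, seed=s))
            r2 = random_search(prob.fitness, prob.bounds, r1.evaluations, seed=s)
            nmr.append(-r1.best_fitness)
            rnd.append(-r2.best_fitness)
        assert np.median(nmr) < np.median(rnd)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 1000))
def test_history_nondecreasing_property(seed):
    """Greedy replacement makes best-so-far monotone for any seed."""
    prob = benchmark_function("rastrigin", 2)
    res = optimize(prob.fitness, prob.bounds, NMRConfig(pop_size=6, epochs=8, seed=seed))
    assert np.all(np.diff(res.history) >= 0)
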