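"""Unit and property tests for the continuous optimizer machinery."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bisma.core import (
    ISMAParams,
    InvalidProblemError,
    Population,
    Problem,
    SMAParams,
    cauchy_refine_best,
    cauchy_sample,
    compute_a,
    compute_b,
    compute_p,
    compute_weights,
    de_crossover,
    de_mutation,
    initialize_population,
    mc_refine_best,
    run_isma,
    run_sma,
    sma_position_update,
)


def sphere(x):
    return float(np.sum(np.asarray(x) ** 2))


# ---------------------------------------------------------------------------
# problem / initialization


class TestProblem:
    def test_rejects_nonfinite_bounds(self):
        with pytest.raises(InvalidProblemError):
            Problem(dimension=2, lower=[0, -np.inf], upper=[1, 1], objective=sphere)

    def test_rejects_inverted_bounds(self):
        with pytest.raises(InvalidProblemError):
            Problem(dimension=1, lower=1.0, upper=0.0, objective=sphere)

    def test_clamp_clip_and_reflect(self):
        p = Problem(dimension=2, lower=0.0, upper=1.0, objective=sphere)
        np.testing.assert_allclose(p.clamp(np.array([-0.5, 1.5])), [0.0, 1.0])
        np.testing.assert_allclose(
            p.clamp(np.array([-0.25, 1.25]), mode="reflect"), [0.25, 0.75]
        )


class TestInitialization:
    def test_degenerate_box_pins_positions(self, rng):
        eps = 1e-12
        p = Problem(dimension=3, lower=0.0, upper=eps, objective=sphere)
        pop = initialize_population(p, SMAParams(population_size=4), rng)
        assert np.all(np.abs(pop.positions) <= eps)

    def test_unit_box_init_sets_elite(self, rng):
        p = Problem(dimension=1, lower=0.0, upper=1.0, objective=sphere)
        pop = initialize_population(p, SMAParams(population_size=4, seed=0), rng)
        assert pop.positions.shape == (4, 1)
        assert np.all((pop.positions >= 0) & (pop.positions <= 1))
        assert pop.best_fitness == pytest.approx(float(pop.fitnesses.min()))

    def test_fitness_matches_bruteforce_reevaluation(self, rng):
        p = Problem(dimension=30, lower=-100.0, upper=100.0, objective=sphere)
        pop = initialize_population(p, SMAParams(population_size=30, seed=7), rng)
        expected = min(sum(v * v for v in row) for row in pop.positions)
        assert pop.best_fitness == pytest.approx(expected, rel=1e-13)


# ---------------------------------------------------------------------------
# scalar helpers


class TestScalarHelpers:
    def test_p_at_elite_is_zero(self):
        assert compute_p(3.0, 3.0) == 0.0

    def test_p_saturates_toward_one(self):
        assert compute_p(1e9, 0.0) == pytest.approx(1.0)
        assert compute_p(1.0, 0.0) == pytest.approx(math.tanh(1.0), abs=1e-15)

    @given(st.floats(-9, 9), st.floats(-9, 9))
    def test_p_in_unit_interval(self, s, df):
        # strictly below 1 wherever double precision can represent the gap
        assert 0.0 <= compute_p(s, df) < 1.0

    def test_a_b_endpoints(self):
        assert compute_a(10, 10) == 0.0
        assert compute_b(10, 10) == 0.0
        assert compute_b(5, 10) == pytest.approx(0.5)
        assert compute_a(1, 10) == pytest.approx(math.atanh(0.9), abs=1e-15)

    def test_iteration_counter_must_start_at_one(self):
        with pytest.raises(ValueError):
            compute_a(0, 10)


class TestWeights:
    def test_equal_fitnesses_give_unit_weights(self, rng):
        w = compute_weights(np.full(6, 2.5), 3, rng)
        np.testing.assert_array_equal(w, np.ones((6, 3)))

    def test_two_agent_hand_expansion(self):
        # ratio is 0 for the best agent (W = 1) and 1 for the worst
        # (W = 1 - r*log10(2)); reproduce the stream to recover r
        rng = np.random.default_rng(3)
        w = compute_weights(np.array([0.0, 1.0]), 1, rng)
        r = np.random.default_rng(3).random((2, 1))
        assert w[0, 0] == pytest.approx(1.0)
        assert w[1, 0] == pytest.approx(1.0 - r[1, 0] * math.log10(2.0))

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=12), st.integers(0, 2**31 - 1))
    def test_weights_bounded(self, fits, seed):
        w = compute_weights(np.array(fits), 4, np.random.default_rng(seed))
        lo, hi = 1.0 - math.log10(2.0), 1.0 + math.log10(2.0)
        assert np.all(w >= lo - 1e-12) and np.all(w <= hi + 1e-12)


# ---------------------------------------------------------------------------
# position update


class TestPositionUpdate:
    def _pop(self, problem, n, seed):
        return initialize_population(
            problem, SMAParams(population_size=n, seed=seed), np.random.default_rng(seed)
        )

    def test_z_one_forces_uniform_reseeding(self, sphere_problem):
        rng = np.random.default_rng(0)
        params = SMAParams(population_size=4, max_iter=10, z=1.0)
        pop = self._pop(sphere_problem, 4, 0)
        pop.weights = compute_weights(pop.fitnesses, 2, rng)
        before = pop.positions.copy()
        sma_position_update(pop, sphere_problem, params, 1, rng, 10)
        assert not np.allclose(pop.positions, before)
        assert np.all(np.abs(pop.positions) <= 10.0)

    def test_final_iteration_degenerates(self, sphere_problem):
        # at t = T both vb and vc are 0: branch 2 returns the elite, branch 3
        # the zero vector
        rng = np.random.default_rng(5)
        params = SMAParams(population_size=4, max_iter=3, z=0.0)
        pop = self._pop(sphere_problem, 4, 5)
        pop.weights = compute_weights(pop.fitnesses, 2, rng)
        elite = pop.best_position.copy()
        sma_position_update(pop, sphere_problem, params, 3, rng, 3)
        for row in pop.positions:
            assert np.allclose(row, elite) or np.allclose(row, 0.0)

    def test_positions_stay_in_bounds(self, sphere_problem):
        rng = np.random.default_rng(11)
        params = SMAParams(population_size=6, max_iter=5)
        pop = self._pop(sphere_problem, 6, 11)
        for t in range(1, 6):
            pop.weights = compute_weights(pop.fitnesses, 2, rng)
            sma_position_update(pop, sphere_problem, params, t, rng, 5)
            assert np.all(pop.positions >= sphere_problem.lower)
            assert np.all(pop.positions <= sphere_problem.upper)


# ---------------------------------------------------------------------------
# refinement operators


class TestCauchy:
    def test_median_draw_is_zero(self):
        class MidRng:
            def random(self, size=None):
                return 0.5 if size is None else np.full(size, 0.5)

        assert cauchy_sample(1.0, MidRng()) == pytest.approx(0.0)

    def test_quartile_draw_is_scale(self):
        class QRng:
            def random(self, size=None):
                return 0.75 if size is None else np.full(size, 0.75)

        assert cauchy_sample(2.0, QRng()) == pytest.approx(2.0)

    def test_empirical_cdf_matches_analytic(self):
        rng = np.random.default_rng(42)
        draws = np.sort([cauchy_sample(1.0, rng) for _ in range(10_000)])
        analytic = 0.5 + np.arctan(draws) / np.pi
        empirical = np.arange(1, draws.size + 1) / draws.size
        assert np.max(np.abs(empirical - analytic)) < 0.02

    def test_zero_elite_is_fixed_point(self, sphere_problem):
        pop = Population(
            positions=np.zeros((4, 2)),
            fitnesses=np.zeros(4),
            best_position=np.zeros(2),
            best_fitness=0.0,
        )
        improved = cauchy_refine_best(
            pop, sphere_problem, ISMAParams(population_size=4), np.random.default_rng(0)
        )
        assert not improved
        np.testing.assert_array_equal(pop.best_position, np.zeros(2))

    def test_pinned_improvement_accepted(self):
        # 1-D sphere, elite at 2; a Cauchy draw of -0.9 gives candidate 0.2
        problem = Problem(dimension=1, lower=-10.0, upper=10.0, objective=sphere)
        pop = Population(
            positions=np.array([[2.0]] * 4),
            fitnesses=np.full(4, 4.0),
            best_position=np.array([2.0]),
            best_fitness=4.0,
        )

        class Pinned:
            def random(self, size=None):
                # u such that tan(pi*(u-1/2)) = -0.9
                u = 0.5 + math.atan(-0.9) / math.pi
                return u if size is None else np.full(size, u)

        assert cauchy_refine_best(pop, problem, ISMAParams(population_size=4), Pinned())
        assert pop.best_position[0] == pytest.approx(0.2)
        assert pop.best_fitness == pytest.approx(0.04)


class TestDEOperators:
    def test_identical_partners_return_base(self):
        x = np.array([1.0, 2.0])
        np.testing.assert_array_equal(de_mutation(x, x, x, 0.7), x)

    def test_zero_f_returns_base(self):
        out = de_mutation(np.array([1.0, 1.0]), np.array([5.0, 5.0]), np.array([2.0, 1.0]), 0.0)
        np.testing.assert_array_equal(out, [1.0, 1.0])

    def test_hand_arithmetic(self):
        out = de_mutation(np.array([1.0, 1.0]), np.array([2.0, 0.0]), np.array([0.0, 2.0]), 0.5)
        np.testing.assert_allclose(out, [2.0, 0.0])

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            de_mutation(np.ones(2), np.ones(3), np.ones(2), 0.5)

    def test_pc_one_copies_mutant(self, rng):
        mutant, target = np.arange(5.0), np.zeros(5)
        np.testing.assert_array_equal(de_crossover(mutant, target, 1.0, rng), mutant)

    def test_pc_zero_forces_single_inheritance(self, rng):
        mutant, target = np.ones(6), np.zeros(6)
        trial = de_crossover(mutant, target, 0.0, rng)
        assert trial.sum() == 1.0

    def test_inheritance_rate_matches_expectation(self):
        # P(coordinate from mutant) = Pc + (1-Pc)/D
        rng = np.random.default_rng(2024)
        d, pc, trials = 10, 0.5, 10_000
        mutant, target = np.ones(d), np.zeros(d)
        count = sum(de_crossover(mutant, target, pc, rng).sum() for _ in range(trials))
        p = pc + (1 - pc) / d
        mean, sd = trials * d * p, math.sqrt(trials * d * p * (1 - p))
        assert abs(count - mean) < 3 * sd


class TestMCRefine:
    def test_degenerate_population_cannot_improve(self, sphere_problem):
        x = np.array([1.0, 1.0])
        pop = Population(
            positions=np.tile(x, (5, 1)),
            fitnesses=np.full(5, 2.0),
            best_position=x.copy(),
            best_fitness=2.0,
        )
        assert not mc_refine_best(
            pop, sphere_problem, ISMAParams(population_size=5), np.random.default_rng(1)
        )
        np.testing.assert_array_equal(pop.best_position, x)

    def test_small_population_rejected(self, sphere_problem):
        pop = Population(
            positions=np.zeros((3, 2)),
            fitnesses=np.zeros(3),
            best_position=np.zeros(2),
            best_fitness=0.0,
        )
        with pytest.raises(ValueError):
            mc_refine_best(
                pop, sphere_problem, ISMAParams(population_size=4), np.random.default_rng(0)
            )

    def test_worse_trial_leaves_elite(self, sphere_problem):
        rng = np.random.default_rng(9)
        pop = Population(
            positions=np.array([[0.0, 0.0], [5.0, 5.0], [-5.0, 4.0], [3.0, -6.0]]),
            fitnesses=np.array([0.0, 50.0, 41.0, 45.0]),
            best_position=np.zeros(2),
            best_fitness=0.0,
        )
        assert not mc_refine_best(pop, sphere_problem, ISMAParams(population_size=4), rng)
        assert pop.best_fitness == 0.0


# ---------------------------------------------------------------------------
# full runs


class TestRunIsma:
    def test_single_iteration_z_one_collapses_to_sampling(self, sphere_problem):
        params = ISMAParams(population_size=6, max_iter=1, z=1.0, seed=4)
        res = run_isma(sphere_problem, params)
        assert len(res.history) == 1
        assert res.n_evaluations == 6 + 6 + 2

    def test_ablation_identity_sma(self, sphere_problem):
        params = ISMAParams(
            population_size=8, max_iter=20, seed=99, use_cauchy=False, use_mc=False
        )
        a = run_isma(sphere_problem, params, variant="ISMA")
        b = run_sma(sphere_problem, SMAParams(population_size=8, max_iter=20, seed=99))
        np.testing.assert_array_equal(a.best_position, b.best_position)
        assert a.best_fitness == b.best_fitness
        assert a.history == b.history

    @pytest.mark.parametrize("variant", ["SMA", "CSMA", "MCSMA", "ISMA"])
    def test_history_monotone_and_final_consistent(self, sphere_problem, variant):
        res = run_isma(
            sphere_problem, ISMAParams(population_size=6, max_iter=30, seed=1), variant
        )
        fits = [h[2] for h in res.history]
        assert all(b <= a for a, b in zip(fits, fits[1:]))
        assert fits[-1] == res.best_fitness

    def test_determinism(self, sphere_problem):
        params = ISMAParams(population_size=6, max_iter=15, seed=321)
        a = run_isma(sphere_problem, params)
        b = run_isma(sphere_problem, params)
        np.testing.assert_array_equal(a.best_position, b.best_position)
        assert a.history == b.history

    def test_evaluation_budget_accounting(self, sphere_problem):
        # T = floor(budget/(N+2)); evaluations = N init + T*(N+2)
        params = ISMAParams(population_size=6, max_iter=None, max_evaluations=100, seed=0)
        res = run_isma(sphere_problem, params)
        assert len(res.history) == 100 // 8
        assert res.n_evaluations == 6 + len(res.history) * 8

    def test_evaluations_scale_linearly_in_nt(self, sphere_problem):
        base = run_isma(sphere_problem, ISMAParams(population_size=6, max_iter=10, seed=0))
        double_t = run_isma(sphere_problem, ISMAParams(population_size=6, max_iter=20, seed=0))
        double_n = run_isma(sphere_problem, ISMAParams(population_size=12, max_iter=10, seed=0))
        assert double_t.n_evaluations - 6 == 2 * (base.n_evaluations - 6)
        assert (double_n.n_evaluations - 12) == 10 * 14
        assert (base.n_evaluations - 6) == 10 * 8
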