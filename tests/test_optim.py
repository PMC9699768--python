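"""Dragonfly and bowerbird optimizers: behavior vectors, update rules,
selection probabilities, elitism and bounds invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strokecad.errors import InputError, RunError
from strokecad.optim import (
    Bounds,
    BowerPopulation,
    DFOConfig,
    DragonflySwarm,
    SBOConfig,
    dfo_behaviors,
    dfo_step,
    fitness_error_rate,
    idfo_initialize,
    idfo_run,
    merge_and_truncate,
    sbo_initialize,
    sbo_mutate,
    sbo_probabilities,
    sbo_run,
    sbo_update,
)


def make_swarm(positions, steps=None, food=None, enemy=None, coeffs=(0, 0, 0, 0, 0, 1.0),
               radius=10.0):
    positions = np.asarray(positions, dtype=float)
    n, d = positions.shape
    return DragonflySwarm(
        positions=positions,
        steps=np.zeros((n, d)) if steps is None else np.asarray(steps, dtype=float),
        food=np.zeros(d) if food is None else np.asarray(food, dtype=float),
        enemy=np.zeros(d) if enemy is None else np.asarray(enemy, dtype=float),
        coefficients=coeffs,
        neighborhood_radius=radius,
    )


class TestDFOBehaviors:
    def test_coincident_neighbor_gives_zero_separation_and_cohesion(self):
        swarm = make_swarm([[1.0, 2.0], [1.0, 2.0]])
        S, A, C, F, E = dfo_behaviors(swarm, 0)
        assert np.all(S == 0) and np.all(C == 0)

    def test_alignment_is_mean_neighbor_velocity(self):
        swarm = make_swarm([[0, 0], [1, 0], [0, 1]], steps=[[9, 9], [1, 0], [3, 0]])
        _, A, _, _, _ = dfo_behaviors(swarm, 0)
        np.testing.assert_allclose(A, [2.0, 0.0])

    def test_food_attraction_is_difference(self):
        swarm = make_swarm([[1.0], [1.5]], food=[4.0])
        *_, F, _ = dfo_behaviors(swarm, 0)
        np.testing.assert_allclose(F, [3.0])

    def test_enemy_term_as_printed_and_outward(self):
        swarm = make_swarm([[1.0], [1.5]], enemy=[10.0])
        *_, E = dfo_behaviors(swarm, 0)
        np.testing.assert_allclose(E, [11.0])  # X- + X, exactly as published
        swarm.enemy_formula = "outward"
        *_, E = dfo_behaviors(swarm, 0)
        np.testing.assert_allclose(E, [9.0])

    def test_isolated_individual_has_zero_social_terms(self):
        swarm = make_swarm([[0.0], [100.0]], radius=1.0)
        S, A, C, _, _ = dfo_behaviors(swarm, 0)
        assert np.all(S == 0) and np.all(A == 0) and np.all(C == 0)


class TestDFOStep:
    def test_identity_update(self):
        # all behavior coefficients zero, w=1, zero steps -> swarm unchanged
        swarm = make_swarm([[0.5, 0.5], [0.6, 0.6]], coeffs=(0, 0, 0, 0, 0, 1.0))
        out = dfo_step(swarm, Bounds.cube(0, 1, 2), np.random.default_rng(0))
        np.testing.assert_array_equal(out.positions, swarm.positions)
        np.testing.assert_array_equal(out.steps, swarm.steps)

    def test_pure_food_attraction_moves_toward_food(self):
        swarm = make_swarm([[0.1, 0.9], [0.2, 0.8]], food=[0.5, 0.5],
                           coeffs=(0, 0, 0, 0.5, 0, 0.0))
        out = dfo_step(swarm, Bounds.cube(0, 1, 2), np.random.default_rng(0))
        moved = out.positions - swarm.positions
        toward = swarm.food - swarm.positions
        assert np.all(np.sign(moved) == np.sign(toward))

    def test_positions_clamped_to_bounds(self):
        swarm = make_swarm([[0.95], [0.96]], steps=[[0.5], [0.5]],
                           coeffs=(0, 0, 0, 0, 0, 1.0))
        out = dfo_step(swarm, Bounds.cube(0, 1, 1), np.random.default_rng(0))
        np.testing.assert_allclose(out.positions, [[1.0], [1.0]])

    def test_step_clipped_to_max_fraction(self):
        swarm = make_swarm([[0.0], [0.05]], food=[1.0], coeffs=(0, 0, 0, 10.0, 0, 0.0))
        out = dfo_step(swarm, Bounds.cube(0, 1, 1), np.random.default_rng(0),
                       max_step_fraction=0.1)
        assert np.all(np.abs(out.steps) <= 0.1 + 1e-12)


class TestInitialization:
    @pytest.mark.parametrize("init", [idfo_initialize, sbo_initialize])
    def test_uniform_mean_near_half(self, init):
        obj = init(1000, Bounds.cube(0, 1, 3), seed=4)
        np.testing.assert_array_less(0.45, obj.positions.mean(axis=0))
        np.testing.assert_array_less(obj.positions.mean(axis=0), 0.55)

    @pytest.mark.parametrize("init", [idfo_initialize, sbo_initialize])
    def test_determinism_and_tight_bounds(self, init):
        b = Bounds.cube(0, 1e-9, 2)
        a = init(10, b, seed=3)
        assert np.all(a.positions <= 1e-9)
        assert np.array_equal(a.positions, init(10, b, seed=3).positions)

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(InputError):
            Bounds(np.zeros(2), np.zeros(2))


class TestIDFORun:
    def test_constant_objective_flat_trace(self):
        h = idfo_run(lambda x: 3.5, Bounds.cube(-1, 1, 2), DFOConfig(n=5, iterations=20, seed=1))
        assert h.best_fitness_per_iteration == [3.5] * 20

    def test_single_iteration_returns_best_of_initial_population(self):
        h = idfo_run(lambda x: float(np.sum(x**2)), Bounds.cube(-1, 1, 3),
                     DFOConfig(n=8, iterations=1, seed=2))
        assert len(h.best_fitness_per_iteration) == 1
        assert h.evaluations == 8
        assert h.best_fitness == pytest.approx(float(np.sum(h.best_position**2)))

    def test_nonfinite_objective_raises_run_error(self):
        with pytest.raises(RunError):
            idfo_run(lambda x: np.nan, Bounds.cube(-1, 1, 2), DFOConfig(n=4, iterations=2, seed=0))

    def test_trace_non_increasing_and_best_in_bounds(self):
        b = Bounds.cube(-3, 3, 4)
        h = idfo_run(lambda x: float(np.sum(np.abs(x))), b,
                     DFOConfig(n=10, iterations=60, seed=9))
        trace = h.best_fitness_per_iteration
        assert all(a >= b2 for a, b2 in zip(trace, trace[1:]))
        assert np.all(h.best_position >= b.var_min) and np.all(h.best_position <= b.var_max)


class TestSBOProbabilities:
    def test_published_cost_transform(self):
        pop = BowerPopulation(positions=np.zeros((2, 1)), fitness=np.array([0.0, 1.0]))
        probs = sbo_probabilities(pop)
        np.testing.assert_allclose(pop.costs, [1.0, 0.5])
        np.testing.assert_allclose(probs, [2 / 3, 1 / 3])

    def test_zero_fitness_cost_is_one(self):
        pop = BowerPopulation(positions=np.zeros((1, 1)), fitness=np.array([0.0]))
        sbo_probabilities(pop)
        assert pop.costs[0] == 1.0

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=2, max_size=20))
    def test_valid_probability_vector_for_any_finite_fitness_mix(self, fitness):
        pop = BowerPopulation(positions=np.zeros((len(fitness), 1)),
                              fitness=np.array(fitness))
        probs = sbo_probabilities(pop)
        assert np.all(probs >= 0)
        assert probs.sum() == pytest.approx(1.0)

    def test_roulette_frequencies_match_multinomial(self):
        # selection frequencies over 1e5 draws within 3 sd of expectation
        probs = np.array([0.5, 0.3, 0.15, 0.05])
        pop = BowerPopulation(positions=np.arange(4.0)[:, None], fitness=np.zeros(4))
        pop.probs, pop.costs = probs, probs.copy()
        pop.elite = np.array([0.0])
        rng = np.random.default_rng(77)
        n_draws = 100_000
        # each sbo_update call draws one target per individual-dimension
        counts = np.zeros(4)
        draws = rng.choice(4, size=n_draws, p=probs)  # the same roulette rule sbo_update uses
        counts = np.bincount(draws, minlength=4)
        expected = n_draws * probs
        sd = np.sqrt(n_draws * probs * (1 - probs))
        assert np.all(np.abs(counts - expected) <= 3 * sd)


class TestSBOUpdateMutate:
    def _pop(self, positions, probs, elite, alpha=0.94):
        pop = BowerPopulation(positions=np.asarray(positions, dtype=float),
                              fitness=np.zeros(len(positions)), alpha=alpha)
        pop.probs = np.asarray(probs, dtype=float)
        pop.costs = pop.probs.copy()
        pop.elite = np.asarray(elite, dtype=float)
        return pop

    def test_worked_attraction_example(self):
        # x_old=0, target x_j=2, elite=4, beta=0.5 -> new = 0 + 0.5*((2+4)/2 - 0) = 1.5
        pop = self._pop([[0.0], [2.0]], probs=[0.0, 1.0], elite=[4.0], alpha=1.0)
        new = sbo_update(pop, Bounds.cube(-10, 10, 1), np.random.default_rng(0))
        assert new[0, 0] == pytest.approx(1.5)  # j=1 forced, beta = 1/(1+1)

    def test_fixed_point_when_everything_coincides(self):
        pop = self._pop([[3.0], [3.0]], probs=[0.5, 0.5], elite=[3.0])
        new = sbo_update(pop, Bounds.cube(-10, 10, 1), np.random.default_rng(0))
        np.testing.assert_allclose(new, pop.positions)

    def test_alpha_zero_is_identity(self):
        pop = self._pop([[1.0, 2.0], [3.0, 4.0]], probs=[0.5, 0.5], elite=[0.0, 0.0], alpha=0.0)
        new = sbo_update(pop, Bounds.cube(-10, 10, 2), np.random.default_rng(0))
        np.testing.assert_allclose(new, pop.positions)

    def test_mutation_identity_cases(self):
        rng = np.random.default_rng(1)
        x = rng.random((5, 3))
        b = Bounds.cube(0, 1, 3)
        np.testing.assert_array_equal(sbo_mutate(x, b, rng, z=0.02, mutation_prob=0.0), x)
        np.testing.assert_array_equal(sbo_mutate(x, b, rng, z=0.0, mutation_prob=1.0), x)

    def test_mutation_displacement_sd_matches_sigma(self):
        # sigma = Z * (VarMax - VarMin) = 0.02 on [0, 1]
        rng = np.random.default_rng(2)
        x = np.full((10_000, 1), 0.5)
        out = sbo_mutate(x, Bounds.cube(0, 1, 1), rng, z=0.02, mutation_prob=1.0)
        sd = np.std(out - x)
        assert 0.018 <= sd <= 0.022

    def test_merge_and_truncate_keeps_n_smallest(self):
        rng = np.random.default_rng(3)
        old_f, new_f = rng.random(12), rng.random(12)
        old_p, new_p = rng.random((12, 2)), rng.random((12, 2))
        pos, fit = merge_and_truncate(old_p, old_f, new_p, new_f, 12)
        expected = np.sort(np.concatenate([old_f, new_f]))[:12]  # brute-force oracle
        np.testing.assert_allclose(fit, expected)
        all_pos = np.vstack([old_p, new_p])
        all_fit = np.concatenate([old_f, new_f])
        for p, f in zip(pos, fit):
            assert any(np.array_equal(p, q) and f == g for q, g in zip(all_pos, all_fit))


class TestSBORun:
    def test_constant_objective_flat_trace(self):
        h = sbo_run(lambda x: -2.0, Bounds.cube(-1, 1, 2), SBOConfig(n=5, iterations=15, seed=1))
        assert h.best_fitness_per_iteration == [-2.0] * 16

    def test_trace_non_increasing_and_positions_in_bounds(self):
        b = Bounds.cube(-2, 2, 3)
        h = sbo_run(lambda x: float(np.sum(x**2)), b, SBOConfig(n=8, iterations=40, seed=5))
        trace = h.best_fitness_per_iteration
        assert all(a >= c for a, c in zip(trace, trace[1:]))
        assert np.all(h.best_position >= b.var_min) and np.all(h.best_position <= b.var_max)

    def test_injected_initial_position_is_never_lost(self):
        good = np.array([0.01, 0.01])
        h = sbo_run(lambda x: float(np.sum(x**2)), Bounds.cube(-5, 5, 2),
                    SBOConfig(n=6, iterations=5, seed=8, initial_positions=good[None]))
        assert h.best_fitness <= float(np.sum(good**2))


class TestFitnessErrorRate:
    def test_basic_rates(self):
        assert fitness_error_rate([0, 1, 2], [0, 1, 2]) == 0.0
        assert fitness_error_rate([0] * 5 + [1] * 5, [1] * 5 + [1] * 5) == 50.0

    def test_misclassification_percentage_from_class_counts(self):
        # diagonal counts 25,20,23,54,26,23 against sizes 25,25,24,54,26,24:
        # 171 correct of 178 -> error 100*7/178
        diag = [25, 20, 23, 54, 26, 23]
        sizes = [25, 25, 24, 54, 26, 24]
        true, pred = [], []
        for c, (d, s) in enumerate(zip(diag, sizes)):
            true += [c] * s
            pred += [c] * d + [(c + 1) % 6] * (s - d)
        assert fitness_error_rate(pred, true) == pytest.approx(100 * 7 / 178)
        assert fitness_error_rate(pred, true) == pytest.approx(3.93, abs=0.005)

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            fitness_error_rate([], [])
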