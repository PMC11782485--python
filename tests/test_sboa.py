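import numpy as np
import pytest

from sboakelm.problems import ObjectiveProblem, SearchSpace, get_problem
from sboakelm.sboa import (
    OptimizerConfig,
    SwarmState,
    _SIGMA,
    clip_to_bounds,
    escape_update,
    greedy_select,
    hunting_stage,
    hunting_update_sboa,
    initialize_population,
    levy_flight,
    run_reference_pso,
    run_sboa,
)


def make_state(positions, fitness, gbest=None):
    positions = np.asarray(positions, dtype=float)
    fitness = np.asarray(fitness, dtype=float)
    best = int(np.argmin(fitness))
    return SwarmState(
        positions=positions.copy(),
        fitness=fitness.copy(),
        velocities=np.zeros_like(positions),
        pbest_positions=positions.copy(),
        pbest_fitness=fitness.copy(),
        gbest_position=(positions[best] if gbest is None else np.asarray(gbest, float)).copy(),
        gbest_fitness=float(fitness[best]),
    )


class TestInitialization:
    def test_degenerate_box_collapses(self, rng):
        space = SearchSpace.cube(4, 5.0, 5.0)
        assert np.all(initialize_population(space, 6, rng) == 5.0)

    def test_unit_box_in_bounds(self, rng):
        x = initialize_population(SearchSpace.cube(10, 0.0, 1.0), 30, rng)
        assert x.shape == (30, 10)
        assert np.all((x >= 0.0) & (x <= 1.0))

    def test_default_population_shape(self, rng):
        x = initialize_population(SearchSpace.cube(30, -100, 100), 30, rng)
        assert x.shape == (30, 30)


class TestLevyFlight:
    def test_sigma_constant(self):
        # Mantegna closed form at eta = 1.5, frozen from a direct evaluation
        assert _SIGMA == pytest.approx(0.6965745025576968, abs=1e-14)

    def test_empty_dimension(self, rng):
        assert levy_flight(0, rng).size == 0

    def test_pinned_draws_closed_form(self, pinned_rng):
        # u = v = 1 => RL_j = 0.5 * 0.01 * sigma
        rl = levy_flight(4, pinned_rng(normal=1.0))
        assert np.allclose(rl, 0.005 * _SIGMA, atol=1e-15)

    def test_heavy_tail_versus_normal(self, rng):
        # |v|^(1/eta) in the denominator produces occasional huge steps
        steps = levy_flight(1, rng, size=20000).ravel()
        assert np.max(np.abs(steps)) > 50 * np.median(np.abs(steps))


class TestHuntingStages:
    @pytest.mark.parametrize(
        "iteration,t_max,expected",
        [
            (1, 500, 1),
            (166, 500, 1),
            (167, 500, 2),
            (333, 500, 2),
            (334, 500, 3),
            (500, 500, 3),
            (1, 3, 1),
            (2, 3, 2),
            (3, 3, 3),
        ],
    )
    def test_stage_boundaries(self, iteration, t_max, expected):
        assert hunting_stage(iteration, t_max) == expected

    def test_p1_with_coincident_peers_is_identity(self, rng):
        # with N = 2, both peer picks must name the same (only) other row,
        # so the differential term vanishes
        state = make_state([[1.0, 2.0], [3.0, 4.0]], [1.0, 2.0])
        proposals = hunting_update_sboa(state, 1, 500, rng)
        assert np.array_equal(proposals, state.positions)

    def test_p2_pinned_draws_hand_formula(self, pinned_rng):
        state = make_state([[0.0, 0.0], [2.0, 2.0]], [0.0, 8.0])
        it, t_max = 250, 500
        proposals = hunting_update_sboa(state, it, t_max, pinned_rng(normal=1.0))
        scale = np.exp((it / t_max) ** 4) * (1.0 - 0.5)
        expected = state.gbest_position + scale * (state.gbest_position - state.positions)
        assert np.allclose(proposals, expected, atol=1e-14)

    def test_p2_centered_draws_return_best(self, pinned_rng):
        # RB pinned at 0.5 zeroes the Brownian factor: proposal = x_best
        state = make_state([[0.0, 0.0], [2.0, 2.0]], [0.0, 8.0])
        proposals = hunting_update_sboa(state, 250, 500, pinned_rng(normal=0.5))
        assert np.allclose(proposals, state.gbest_position)

    def test_p3_damping_formula(self, pinned_rng):
        state = make_state([[1.0, 1.0], [2.0, 2.0]], [2.0, 8.0])
        it, t_max = 400, 500
        proposals = hunting_update_sboa(state, it, t_max, pinned_rng(normal=1.0))
        rl = 0.005 * _SIGMA
        damp = (1.0 - it / t_max) ** (2.0 * it / t_max)
        expected = state.gbest_position + damp * state.positions * rl
        assert np.allclose(proposals, expected, atol=1e-14)


class TestEscape:
    def test_s1_collapses_to_best_at_final_iteration(self, pinned_rng):
        # branch draw 0.3 < q = 0.5 forces S1; (1 - T/T)^2 = 0
        state = make_state([[1.0, 1.0], [2.0, 2.0]], [2.0, 8.0])
        proposals = escape_update(state, 500, 500, pinned_rng(uniform=0.3, normal=1.0))
        assert np.allclose(proposals, state.gbest_position)

    def test_s2_identical_rows_are_stationary(self, pinned_rng):
        # branch draw 0.9 forces S2; with all rows equal and l = 1 the
        # camouflage term x_rand - l*x_i is the zero vector
        state = make_state([[1.5, -2.0], [1.5, -2.0]], [3.0, 3.0])
        proposals = escape_update(
            state, 10, 500, pinned_rng(uniform=0.9, integer=[0, 1], normal=1.0)
        )
        # first integers call picks the peer (the other row), second pins l = 1
        assert np.allclose(proposals, state.positions)


class TestGreedySelect:
    def test_elementwise_accept_reject(self):
        state = make_state(np.arange(10.0).reshape(5, 2), [5.0, 1.0, 3.0, 3.0, 9.0])
        proposals = state.positions + 100.0
        prop_fit = np.array([4.0, 2.0, 3.0, 2.9, 0.5])
        expected_accept = prop_fit < state.fitness  # [T, F, F(tie-free), T, T]
        old = state.positions.copy()
        greedy_select(state, proposals, prop_fit)
        for i, acc in enumerate(expected_accept):
            assert np.array_equal(state.positions[i], proposals[i] if acc else old[i])
        assert state.gbest_fitness == 0.5

    def test_ties_keep_incumbent(self):
        state = make_state([[0.0], [1.0]], [1.0, 2.0])
        greedy_select(state, np.array([[9.0], [9.0]]), np.array([1.0, 2.0]))
        assert np.array_equal(state.positions, [[0.0], [1.0]])


class TestClip:
    def test_clip_examples(self):
        space = SearchSpace(2, np.array([-1.0, -1.0]), np.array([1.0, 1.0]))
        out = clip_to_bounds(np.array([[0.5, 1.2], [-3.0, 0.0]]), space)
        assert np.array_equal(out, [[0.5, 1.0], [-1.0, 0.0]])


class TestRunSboa:
    def test_history_monotone_and_bookkeeping(self):
        problem = get_problem("sphere", 2)
        result = run_sboa(problem, OptimizerConfig(pop_size=10, max_iter=50, seed=7))
        assert result.history.size == 50
        assert np.all(np.diff(result.history) <= 0)
        assert result.best_fitness == result.history[-1]
        assert result.n_evaluations == 10 + 2 * 10 * 50

    def test_minimum_iteration_history(self):
        result = run_sboa(get_problem("sphere", 2), OptimizerConfig(pop_size=4, max_iter=3, seed=0))
        assert result.history.size == 3

    def test_same_seed_bit_identical(self):
        problem = get_problem("rastrigin", 3)
        cfg = OptimizerConfig(pop_size=8, max_iter=40, seed=3)
        a = run_sboa(problem, cfg)
        b = run_sboa(problem, cfg)
        assert np.array_equal(a.history, b.history)
        assert np.array_equal(a.best_position, b.best_position)

    def test_constant_objective_never_replaces(self):
        # strict-inequality selection: fitness can never improve
        problem = ObjectiveProblem("flat", SearchSpace.cube(3, -1, 1), lambda x: 7.0)
        result = run_sboa(problem, OptimizerConfig(pop_size=2, max_iter=10, seed=1))
        assert np.all(result.history == 7.0)

    def test_all_evaluated_positions_in_bounds(self):
        space = SearchSpace.cube(3, -0.5, 0.5)
        violations = []

        def spy(x):
            violations.append(np.max([np.max(x - space.ub), np.max(space.lb - x), 0.0]))
            return float(np.sum(x * x))

        problem = ObjectiveProblem("spy", space, spy)
        run_sboa(problem, OptimizerConfig(pop_size=6, max_iter=30, seed=2))
        assert max(violations) == 0.0


class TestReferencePso:
    def test_converges_below_initial(self):
        problem = get_problem("sphere", 10)
        result = run_reference_pso(problem, OptimizerConfig(pop_size=20, max_iter=100, seed=1))
        assert result.best_fitness < result.history[0]
        assert np.all(np.diff(result.history) <= 0)

    def test_deterministic(self):
        problem = get_problem("ackley", 5)
        cfg = OptimizerConfig(pop_size=10, max_iter=30, seed=9)
        assert np.array_equal(
            run_reference_pso(problem, cfg).history, run_reference_pso(problem, cfg).history
        )
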