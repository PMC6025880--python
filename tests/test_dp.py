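"""Dynamic-programming solvers: active, passive, known-model, evaluation."""

import math

import numpy as np
import pytest

import amvoi


class TestSolveActive:
    def test_single_stage_maximizes_immediate_reward(self):
        P = np.full((1, 2, 2, 2), 0.5)
        R = np.array([[1.0, 0.2], [0.4, 0.9]])
        problem = amvoi.DecisionProblem(
            ("a", "b"), ("x", "y"), ("m",), P, R, discount=0.5, horizon=1
        )
        grid = amvoi.build_belief_grid(1, 1.0)
        V, pol = amvoi.solve_active(problem, grid)
        np.testing.assert_allclose(V.values[:, 0], [1.0, 0.9])
        np.testing.assert_array_equal(pol.actions[:, 0], [0, 1])

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_expectimax_oracle(self, seed, oracle):
        """Grid DP equals exhaustive expectimax on tiny instances."""
        rng_sizes = np.random.default_rng(seed)
        S = int(rng_sizes.integers(2, 4))
        A = int(rng_sizes.integers(2, 4))
        T = int(rng_sizes.integers(1, 4))
        problem = amvoi.random_problem(S, A, 2, seed=seed, discount=1.0, horizon=T)
        grid = amvoi.build_belief_grid(2, 0.01)
        V, _ = amvoi.solve_active(problem, grid)
        for q0 in (0.0, 0.25, 0.5, 0.9, 1.0):
            q = np.array([q0, 1 - q0])
            for x in range(S):
                exact = oracle(problem, x, q, T)
                assert V.at(x, q) == pytest.approx(exact, abs=1e-3)

    def test_vertex_consistency_with_known_model(self, two_model_toy):
        grid = amvoi.build_belief_grid(2, 0.1)
        V, _ = amvoi.solve_active(two_model_toy, grid)
        for k in range(2):
            vk, _ = amvoi.solve_known_model(two_model_toy, k)
            np.testing.assert_allclose(
                V.values[:, grid.vertex_index(k)], vk, atol=1e-8
            )

    def test_reward_shift_raises_values_by_annuity(self, two_model_toy):
        """Adding c to every reward adds c * sum_t lambda^t to every value."""
        grid = amvoi.build_belief_grid(2, 0.25)
        problem = two_model_toy.replace(discount=0.9)
        V0, _ = amvoi.solve_active(problem, grid)
        shifted = problem.replace(rewards=problem.rewards + 2.5)
        V1, _ = amvoi.solve_active(shifted, grid)
        T = int(problem.horizon)
        annuity = 2.5 * sum(problem.discount**t for t in range(T))
        np.testing.assert_allclose(V1.values, V0.values + annuity, atol=1e-10)

    def test_value_convex_in_belief(self, scrubjay_short):
        """The active value surface is convex in q up to interpolation error."""
        problem, _, _ = scrubjay_short
        grid = amvoi.build_belief_grid(2, 0.05)
        V, _ = amvoi.solve_active(problem, grid)
        second_diff = V.values[:, :-2] - 2 * V.values[:, 1:-1] + V.values[:, 2:]
        assert second_diff.min() > -1e-6

    def test_nonconvergence_raises_with_diagnostics(self, two_model_toy):
        problem = two_model_toy.replace(discount=0.99, horizon=math.inf)
        grid = amvoi.build_belief_grid(2, 0.5)
        with pytest.raises(amvoi.ConvergenceError, match="iterations"):
            amvoi.solve_active(problem, grid, max_iter=3)


class TestSolvePassive:
    def test_single_model_equals_active(self):
        problem = amvoi.random_problem(3, 2, 1, seed=7, discount=0.9, horizon=20)
        grid = amvoi.build_belief_grid(1, 1.0)
        Va, _ = amvoi.solve_active(problem, grid)
        Vp, _ = amvoi.solve_passive(problem, grid)
        np.testing.assert_allclose(Va.values, Vp.values, atol=1e-12)

    def test_identical_models_equals_active(self, two_model_toy):
        P = np.stack([two_model_toy.transitions[0]] * 2)
        problem = two_model_toy.replace(transitions=P)
        grid = amvoi.build_belief_grid(2, 0.25)
        Va, _ = amvoi.solve_active(problem, grid)
        Vp, _ = amvoi.solve_passive(problem, grid)
        np.testing.assert_allclose(Va.values, Vp.values, atol=1e-10)

    def test_passive_policy_never_beats_active_value(self, two_model_toy):
        """Evaluating the passive policy under true learning dynamics stays
        below the active optimum everywhere (up to grid tolerance)."""
        grid = amvoi.build_belief_grid(2, 0.05)
        Va, _ = amvoi.solve_active(two_model_toy, grid)
        _, passive_policy = amvoi.solve_passive(two_model_toy, grid)
        Vp = amvoi.evaluate_policy(two_model_toy, passive_policy, grid, "internal")
        assert (Vp.values <= Va.values + 1e-6).all()


class TestSolveKnownModel:
    def test_zero_rewards_give_zero_values(self, two_model_toy):
        problem = two_model_toy.replace(rewards=np.zeros_like(two_model_toy.rewards))
        vk, _ = amvoi.solve_known_model(problem, 0)
        np.testing.assert_array_equal(vk, [0.0, 0.0])

    def test_deterministic_cycle_accumulates_rewards(self):
        # two states cycling deterministically, reward 1 per step, T=3 -> V=3
        P = np.zeros((1, 1, 2, 2))
        P[0, 0] = [[0.0, 1.0], [1.0, 0.0]]
        problem = amvoi.DecisionProblem(
            ("a", "b"), ("go",), ("m",), P, np.ones((1, 2)),
            discount=1.0, horizon=3,
        )
        vk, _ = amvoi.solve_known_model(problem, 0)
        np.testing.assert_allclose(vk, [3.0, 3.0])

    def test_model_index_out_of_range(self, two_model_toy):
        with pytest.raises(amvoi.ValidationError):
            amvoi.solve_known_model(two_model_toy, 5)


class TestEvaluatePolicy:
    def test_optimal_policy_evaluates_to_optimal_value(self, two_model_toy):
        grid = amvoi.build_belief_grid(2, 0.1)
        V, policy = amvoi.solve_active(two_model_toy, grid)
        Ve = amvoi.evaluate_policy(two_model_toy, policy, grid, "internal")
        np.testing.assert_allclose(Ve.values, V.values, atol=1e-8)

    def test_absorbing_chain_hand_value(self):
        """Reward 1 until absorption from state 0 (prob 0.5/step, T=2):
        E = 1 + 0.5 = 1.5 starting outside the absorbing state."""
        P = np.zeros((1, 1, 2, 2))
        P[0, 0] = [[0.5, 0.5], [0.0, 1.0]]
        problem = amvoi.DecisionProblem(
            ("alive", "gone"), ("wait",), ("m",), P,
            np.array([[1.0, 0.0]]), discount=1.0, horizon=2,
        )
        grid = amvoi.build_belief_grid(1, 1.0)
        V = amvoi.evaluate_policy(
            problem, np.zeros((2, 1), dtype=int), grid, "internal"
        )
        assert V.values[0, 0] == pytest.approx(1.5)
        assert V.values[1, 0] == pytest.approx(0.0)

    def test_value_respects_geometric_bound(self):
        problem = amvoi.random_problem(3, 2, 2, seed=3, discount=0.9, horizon=50)
        grid = amvoi.build_belief_grid(2, 0.25)
        _, policy = amvoi.solve_active(problem, grid)
        V = amvoi.evaluate_policy(problem, policy, grid, "none")
        bound = np.abs(problem.rewards).max() * min(
            50, 1 / (1 - problem.discount)
        )
        assert np.abs(V.values).max() <= bound + 1e-9
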