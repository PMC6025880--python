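"""Domain types, validation and Bayesian belief updating."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import amvoi
from amvoi.core import PROB_TOL


def _beliefs(n_models=2):
    return (
        st.lists(
            st.floats(1e-6, 1.0, allow_nan=False), min_size=n_models, max_size=n_models
        )
        .map(lambda w: np.array(w) / np.sum(w))
    )


def _signal_models(n_models=2, n_outcomes=3):
    return (
        st.lists(
            st.lists(st.floats(1e-6, 1.0), min_size=n_outcomes, max_size=n_outcomes),
            min_size=n_models,
            max_size=n_models,
        )
        .map(
            lambda rows: amvoi.SignalModel(
                tuple(f"z{i}" for i in range(n_outcomes)),
                np.array(rows) / np.array(rows).sum(axis=1, keepdims=True),
            )
        )
    )


class TestValidation:
    def test_synthetic_fixture_is_valid(self, scrubjay):
        problem, signal, period = scrubjay
        assert amvoi.validate_problem(problem) == []
        assert period == 2

    def test_minimal_problem_is_valid(self):
        problem = amvoi.DecisionProblem(
            ("s",), ("a",), ("m",), np.ones((1, 1, 1, 1)), np.zeros((1, 1)), horizon=1
        )
        assert amvoi.validate_problem(problem) == []

    def test_bad_row_sum_names_the_row(self):
        P = np.ones((1, 1, 2, 2)) * 0.5
        P[0, 0, 1] = [0.5, 0.4]  # sums to 0.9
        with pytest.raises(amvoi.ValidationError, match=r"model=0.*action=0.*state=1"):
            amvoi.DecisionProblem(("a", "b"), ("x",), ("m",), P, np.zeros((1, 2)), horizon=1)

    def test_structural_error_distinct_from_probability_error(self):
        problem = amvoi.DecisionProblem(
            ("s",), ("a",), ("m",), np.ones((1, 1, 1, 1)), np.zeros((1, 1)), horizon=1
        )
        broken = object.__new__(amvoi.DecisionProblem)
        for f in (
            "state_labels", "action_labels", "model_labels", "rewards",
            "discount", "horizon", "name",
        ):
            object.__setattr__(broken, f, getattr(problem, f))
        object.__setattr__(broken, "transitions", np.ones((1, 1, 1)))
        report = amvoi.validate_problem(broken)
        assert len(report) == 1 and report[0].startswith("structure:")

    def test_infinite_horizon_requires_discounting(self):
        with pytest.raises(amvoi.ValidationError, match="discount"):
            amvoi.DecisionProblem(
                ("s",), ("a",), ("m",), np.ones((1, 1, 1, 1)), np.zeros((1, 1)),
                discount=1.0, horizon=float("inf"),
            )


class TestModelAveraging:
    def test_degenerate_belief_returns_that_model(self, two_model_toy):
        got = amvoi.model_averaged_transition(two_model_toy, [1.0, 0.0], action=0)
        np.testing.assert_array_equal(got, two_model_toy.transitions[0, 0])

    def test_hand_mixture(self):
        # equal weights on cells 0.8 and 0.4 -> 0.6
        P = np.zeros((2, 1, 2, 2))
        P[0, 0] = [[0.8, 0.2], [0.5, 0.5]]
        P[1, 0] = [[0.4, 0.6], [0.5, 0.5]]
        problem = amvoi.DecisionProblem(
            ("a", "b"), ("x",), ("m0", "m1"), P, np.zeros((1, 2)), horizon=1
        )
        got = amvoi.model_averaged_transition(problem, [0.5, 0.5], 0)
        assert got[0, 0] == pytest.approx(0.6)

    @given(q=_beliefs())
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_rows_sum_to_one(self, q):
        P = np.array(
            [
                [[[0.9, 0.1], [0.3, 0.7]]],
                [[[0.2, 0.8], [0.5, 0.5]]],
            ]
        )
        problem = amvoi.DecisionProblem(
            ("a", "b"), ("x",), ("m0", "m1"), P, np.zeros((1, 2)), horizon=1
        )
        kernel = amvoi.model_averaged_transition(problem, q, 0)
        np.testing.assert_allclose(kernel.sum(axis=1), 1.0, atol=PROB_TOL)


class TestInternalUpdate:
    def test_vertex_is_fixed_point(self, two_model_toy):
        q = amvoi.update_internal(two_model_toy, [1.0, 0.0], 0, 0, 1)
        np.testing.assert_array_equal(q, [1.0, 0.0])

    def test_identical_models_leave_belief_unchanged(self, two_model_toy):
        P = np.stack([two_model_toy.transitions[0]] * 2)
        problem = two_model_toy.replace(transitions=P)
        q = amvoi.update_internal(problem, [0.3, 0.7], 0, 1, 1)
        np.testing.assert_allclose(q, [0.3, 0.7], atol=1e-14)

    def test_hand_bayes(self):
        # likelihoods 0.8 vs 0.4 at even prior -> posterior (2/3, 1/3)
        P = np.zeros((2, 1, 2, 2))
        P[0, 0] = [[0.8, 0.2], [0.5, 0.5]]
        P[1, 0] = [[0.4, 0.6], [0.5, 0.5]]
        problem = amvoi.DecisionProblem(
            ("a", "b"), ("x",), ("m0", "m1"), P, np.zeros((1, 2)), horizon=1
        )
        q = amvoi.update_internal(problem, [0.5, 0.5], 0, 0, 0)
        np.testing.assert_allclose(q, [2 / 3, 1 / 3])

    def test_impossible_transition_raises(self):
        P = np.zeros((1, 1, 2, 2))
        P[0, 0] = [[1.0, 0.0], [0.0, 1.0]]
        problem = amvoi.DecisionProblem(("a", "b"), ("x",), ("m",), P, np.zeros((1, 2)), horizon=1)
        with pytest.raises(amvoi.ImpossibleObservationError):
            amvoi.update_internal(problem, [1.0], 0, 0, 1)


class TestExternalUpdate:
    @pytest.fixture
    def signal(self):
        return amvoi.SignalModel(("u", "v"), [[0.9, 0.1], [0.1, 0.9]])

    def test_uninformative_signal_no_change(self):
        flat = amvoi.SignalModel(("u", "v"), [[0.5, 0.5], [0.5, 0.5]])
        q = amvoi.update_external([0.3, 0.7], flat, 0)
        np.testing.assert_allclose(q, [0.3, 0.7])

    def test_vertex_fixed_point(self, signal):
        np.testing.assert_array_equal(
            amvoi.update_external([1.0, 0.0], signal, 1), [1.0, 0.0]
        )

    def test_hand_bayes(self):
        signal = amvoi.SignalModel(("u", "v"), [[0.9, 0.1], [0.1, 0.9]])
        q = amvoi.update_external([0.3, 0.7], signal, 0)
        np.testing.assert_allclose(q, [27 / 34, 7 / 34])

    def test_impossible_outcome_raises(self):
        signal = amvoi.SignalModel(("u", "v"), [[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(amvoi.ImpossibleObservationError):
            amvoi.update_external([0.5, 0.5], signal, 1)

    @given(q=_beliefs(), sig=_signal_models())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_sequential_updates_commute_with_joint_likelihood(self, q, sig):
        """Updating on z then z' equals one update on the product likelihood."""
        try:
            step = amvoi.update_external(amvoi.update_external(q, sig, 0), sig, 1)
        except amvoi.ImpossibleObservationError:
            return
        joint = sig.distributions[:, 0] * sig.distributions[:, 1]
        expected = q * joint / (q @ joint)
        np.testing.assert_allclose(step, expected, atol=1e-12)

    @given(q=_beliefs(), sig=_signal_models())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_preposterior_martingale(self, q, sig):
        """The predictive-weighted average posterior equals the prior."""
        marg = amvoi.signal_marginal(q, sig)
        mean_post = np.zeros_like(q)
        for z, pz in enumerate(marg):
            if pz > 0:
                mean_post += pz * amvoi.update_external(q, sig, z)
        np.testing.assert_allclose(mean_post, q, atol=1e-10)


class TestSignalMarginal:
    def test_degenerate_belief_gives_that_models_law(self):
        sig = amvoi.SignalModel(("u", "v"), [[0.9, 0.1], [0.2, 0.8]])
        np.testing.assert_allclose(
            amvoi.signal_marginal([1.0, 0.0], sig), [0.9, 0.1]
        )

    def test_hand_mixture_and_normalization(self):
        sig = amvoi.SignalModel(("u", "v"), [[0.9, 0.1], [0.1, 0.9]])
        marg = amvoi.signal_marginal([0.5, 0.5], sig)
        assert marg[0] == pytest.approx(0.5)
        assert marg.sum() == pytest.approx(1.0, abs=PROB_TOL)
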