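"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import amvoi


@pytest.fixture(scope="session")
def scrubjay():
    """Synthetic scrub-management fixture: (problem, signal, period)."""
    return amvoi.load_scrubjay_synthetic()


@pytest.fixture(scope="session")
def scrubjay_short(scrubjay):
    """Same problem at a short horizon for cheap solves."""
    problem, signal, period = scrubjay
    return problem.replace(horizon=200), signal, period


@pytest.fixture
def two_model_toy():
    """Tiny 2-state/2-action/2-model problem where the models disagree.

    Model 0 says action 0 keeps the system in the rewarding state 0;
    model 1 says action 1 does.  Learning which model holds is valuable,
    which makes the toy a good probe for active-vs-passive differences.
    """
    P = np.array(
        [  # model 0
            [
                [[0.9, 0.1], [0.9, 0.1]],  # action 0
                [[0.2, 0.8], [0.2, 0.8]],  # action 1
            ],
            [  # model 1
                [[0.2, 0.8], [0.2, 0.8]],
                [[0.9, 0.1], [0.9, 0.1]],
            ],
        ]
    ).reshape(2, 2, 2, 2)
    R = np.array([[1.0, 0.0], [1.0, 0.0]])
    return amvoi.DecisionProblem(
        state_labels=("good", "bad"),
        action_labels=("stay", "switch"),
        model_labels=("m0", "m1"),
        transitions=P,
        rewards=R,
        discount=1.0,
        horizon=3,
        name="two-model-toy",
    )


# ----------------------------------------------------------------------
# independent oracles (no grid, exact beliefs, exhaustive enumeration)


def expectimax(problem: amvoi.DecisionProblem, state: int, belief, steps: int) -> float:
    """Brute-force active-adaptive value by exhaustive expectimax.

    Enumerates every action and every realizable successor, carrying exact
    Bayes posteriors; exponential in ``steps`` and independent of the
    grid-based solver it checks.
    """
    if steps == 0:
        return 0.0
    q = np.asarray(belief, dtype=float)
    P, R, lam = problem.transitions, problem.rewards, problem.discount
    best = -np.inf
    for a in range(problem.n_actions):
        pbar = q @ P[:, a, state, :]
        total = R[a, state]
        for y in range(problem.n_states):
            if pbar[y] <= 0.0:
                continue
            post = q * P[:, a, state, y] / pbar[y]
            total += lam * pbar[y] * expectimax(problem, y, post, steps - 1)
        best = max(best, total)
    return best


def periodic_expectimax(
    problem: amvoi.DecisionProblem, state: int, belief, period: int, blocks: int
) -> float:
    """Brute-force periodic-monitoring value: open-loop blocks of actions.

    For each block the full action sequence is committed up front (out-year
    actions cannot react to unobserved states); beliefs are propagated
    exactly along every realized path and the recursion continues at the
    next observation point.
    """
    if blocks == 0:
        return 0.0
    q = np.asarray(belief, dtype=float)
    P, R, lam = problem.transitions, problem.rewards, problem.discount
    import itertools

    best = -np.inf
    for seq in itertools.product(range(problem.n_actions), repeat=period):
        # branches: (state, probability, belief, depth-summed reward)
        branches = [(state, 1.0, q, 0.0)]
        for j, a in enumerate(seq):
            new = []
            for x, prob, bel, rew in branches:
                rew = rew + (lam**j) * R[a, x]
                pbar = bel @ P[:, a, x, :]
                for y in range(problem.n_states):
                    if pbar[y] <= 0.0:
                        continue
                    post = bel * P[:, a, x, y] / pbar[y]
                    new.append((y, prob * pbar[y], post, rew))
            branches = new
        total = 0.0
        for x, prob, bel, rew in branches:
            total += prob * (
                rew
                + (lam**period)
                * periodic_expectimax(problem, x, bel, period, blocks - 1)
            )
        best = max(best, total)
    return best


@pytest.fixture(scope="session")
def oracle():
    return expectimax


@pytest.fixture(scope="session")
def periodic_oracle():
    return periodic_expectimax
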