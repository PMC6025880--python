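"""Valuation under reduced monitoring frequency.

With monitoring every ``m`` years, the system state is observed at the
start of each ``m``-year block and the block's actions are chosen then: the
in-year action conditions on the observed ``(x, q)`` and out-year actions
condition only on ``(x, q)`` and the actions already committed — never on
the unobserved intermediate states.  At the next observation the full
realized state sequence is folded into the belief by repeated Bayes
updates, branch by branch, so the solver anticipates the learning that the
delayed observation will deliver.

The marginal value of monitoring in an out-year compares the annual-optimal
value against the *averaged* out-year value

``Vbar[x, q, a*] = sum_x' Pbar(x'|x, a*, q) V[x', q'(x')]``

where ``a*`` is the in-year action of the periodic policy: the monitoring
EVSI ``V[x, q] - Vbar[x, q, a*]`` can be negative as well as positive,
because an average of optimal values is compared against the optimal value
of one particular state that may enter that average.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .core import DecisionProblem, ValidationError, as_belief, update_internal
from .dp import (
    DEFAULT_MAX_ITER,
    DEFAULT_TOL,
    PolicySurface,
    ValueSurface,
    _iterate,
    solve_active,
)
from .grid import BeliefGrid, interpolate_value

__all__ = [
    "solve_periodic",
    "outyear_value",
    "monitoring_evsi",
    "monitoring_report",
]


def _block_q_values(
    problem: DecisionProblem, grid: BeliefGrid, V: np.ndarray, period: int
) -> np.ndarray:
    """Block action values ``Q[seq, x, g]`` for all ``A**m`` action sequences.

    Each sequence is an open-loop plan for one monitoring block; branches of
    realized states carry exact, sequentially-updated beliefs and are pruned
    when their probability vanishes on the whole grid.
    """
    P = problem.transitions  # (K, A, S, S)
    R = problem.rewards
    lam = problem.discount
    S, G = problem.n_states, grid.n_points
    Q0 = grid.points
    n_seq = problem.n_actions**period
    out = np.empty((n_seq, S, G))
    for s_i, seq in enumerate(itertools.product(range(problem.n_actions), repeat=period)):
        for x0 in range(S):
            val = np.zeros(G)
            # branch: (current state, path probability per grid point, belief per grid point)
            branches = [(x0, np.ones(G), Q0)]
            for j, a in enumerate(seq):
                new = []
                for xc, prob, bel in branches:
                    val += prob * (lam**j) * R[a, xc]
                    lik = P[:, a, xc, :]  # (K, S)
                    pstep = bel @ lik  # (G, S)
                    for y in range(S):
                        p = pstep[:, y]
                        nprob = prob * p
                        if not np.any(nprob > 0):
                            continue
                        safe = np.where(p > 0, p, 1.0)[:, None]
                        nbel = np.where(p[:, None] > 0, bel * lik[:, y] / safe, bel)
                        new.append((y, nprob, nbel))
                branches = new
            for xm, prob, bel in branches:
                val += (lam**period) * prob * grid.interpolate(V[xm], bel)
            out[s_i, x0] = val
    return out


def solve_periodic(
    problem: DecisionProblem,
    grid: BeliefGrid,
    period: int,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[ValueSurface, PolicySurface]:
    """Optimal value/policy when states are observed every ``period`` years.

    ``period = 1`` reduces to the annual active-adaptive solution.  Finite
    horizons must be divisible by ``period`` (the horizon is optimized in
    whole blocks); infinite horizons iterate the block operator, a
    contraction with modulus ``discount**period``.
    """
    if period < 1:
        raise ValidationError("monitoring period must be >= 1")
    if problem.finite_horizon and int(problem.horizon) % period:
        raise ValidationError(
            f"finite horizon {problem.horizon} is not divisible by period {period}"
        )
    S, G = problem.n_states, grid.n_points
    block = problem if not problem.finite_horizon else problem.replace(
        horizon=problem.horizon / period
    )
    # _iterate counts block backups: finite horizon T/period blocks
    V, its, delta = _iterate(
        lambda V: _block_q_values(problem, grid, V, period).max(axis=0),
        block,
        (S, G),
        tol,
        max_iter,
    )
    qv = _block_q_values(problem, grid, V, period)
    best_seq = qv.argmax(axis=0)  # (S, G), ties -> lexicographically lowest sequence
    seqs = np.array(
        list(itertools.product(range(problem.n_actions), repeat=period)), dtype=np.int64
    )  # (n_seq, m)
    sequences = np.moveaxis(seqs[best_seq], -1, 0)  # (m, S, G)
    meta = {
        "mode": "periodic-active",
        "period": period,
        "discount": problem.discount,
        "horizon": problem.horizon,
        "grid_step": grid.step,
        "tol": tol,
        "iterations": its,
        "final_delta": delta,
        "problem": problem.name,
    }
    return (
        ValueSurface(V, grid, dict(meta)),
        PolicySurface(sequences[0], grid, dict(meta), action_sequences=sequences),
    )


def outyear_value(
    problem: DecisionProblem,
    state: int,
    belief: Sequence[float],
    action: int,
    annual_surface: ValueSurface,
) -> float:
    """Averaged value of the unobserved out-year.

    ``Vbar[x, q, a] = sum_x' Pbar(x'|x, a, q) V[x', q'(x')]`` where ``V`` is
    the annual-optimal surface and ``q'(x')`` the posterior the manager
    *would* hold had ``x'`` been observed.  With monitoring suspended the
    manager cannot condition on ``x'``, so the attainable out-year value is
    this average rather than the realized-state optimum.
    """
    q = as_belief(belief, problem.n_models)
    pbar = q @ problem.transitions[:, action, state, :]  # (S,)
    total = 0.0
    for y in range(problem.n_states):
        if pbar[y] <= 0.0:
            continue
        post = update_internal(problem, q, state, action, y)
        total += pbar[y] * annual_surface.at(y, post)
    return float(total)


def monitoring_evsi(
    problem: DecisionProblem,
    state: int,
    belief: Sequence[float],
    annual_surface: ValueSurface,
    outyear: float,
) -> float:
    """Marginal value of monitoring in the out-year: ``V[x, q] - Vbar``."""
    q = as_belief(belief, problem.n_models)
    return annual_surface.at(state, q) - outyear


def monitoring_report(
    problem: DecisionProblem,
    grid: BeliefGrid,
    q_values: Sequence,
    period: int = 2,
    tol: float = DEFAULT_TOL,
) -> pd.DataFrame:
    """Annual-vs-periodic comparison table over states and chosen beliefs.

    One row per (state, belief): the annual-optimal action and value, the
    periodic policy's out-year action (conditioned on the observed state,
    belief and its own in-year action), the averaged out-year value and the
    monitoring EVSI (annual value minus averaged out-year value).

    ``q_values`` entries are either full belief vectors or, for two-model
    problems, scalars giving the probability of the first model.
    """
    beliefs = []
    for raw_q in q_values:  # validate before paying for the solves
        if np.isscalar(raw_q):
            if problem.n_models != 2:
                raise ValidationError("scalar beliefs only supported for two models")
            q = np.array([float(raw_q), 1.0 - float(raw_q)])
        else:
            q = as_belief(raw_q, problem.n_models)
        beliefs.append((q, _grid_index(grid, q)))
    annual_V, annual_pol = solve_active(problem, grid, tol=tol)
    periodic_V, periodic_pol = solve_periodic(problem, grid, period, tol=tol)
    rows = []
    for q, g in beliefs:
        for x in range(problem.n_states):
            a_annual = int(annual_pol.actions[x, g])
            v_annual = float(annual_V.values[x, g])
            seq = periodic_pol.action_sequences[:, x, g]
            a_in = int(seq[0])
            a_out = int(seq[1]) if period > 1 else a_in
            vbar = outyear_value(problem, x, q, a_in, annual_V)
            rows.append(
                {
                    "state": x + 1,
                    "q": float(q[0]),
                    "annual_action": a_annual + 1,
                    "annual_value": v_annual,
                    "outyear_action": a_out + 1,
                    "outyear_value": vbar,
                    "evsi": v_annual - vbar,
                }
            )
    frame = pd.DataFrame(rows)
    frame.attrs = {
        "problem": problem.name,
        "period": period,
        "grid_step": grid.step,
        "discount": problem.discount,
        "horizon": problem.horizon,
        "state_labels": problem.state_labels,
        "action_labels": problem.action_labels,
        "q_is": f"probability of model {problem.model_labels[0]!r}",
    }
    return frame


def _grid_index(grid: BeliefGrid, q: np.ndarray) -> int:
    idx, w = grid.weights(q[None, :])
    best = int(np.argmax(w[0]))
    if w[0, best] < 1.0 - 1e-9:
        raise ValidationError(
            f"belief {q} is not a grid point (step {grid.step}); "
            "report beliefs must lie on the grid"
        )
    return int(idx[0, best])
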