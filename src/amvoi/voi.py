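"""Expected value of perfect and sample information for adaptive management.

*Perfect* information resolves which candidate model is correct before any
decision is made: its expected value at ``(x, q)`` is the belief-weighted
average of the single-model optimal values minus the optimal value under
uncertainty,

``EVPI = sum_k q(k) V_k[x] - V[x, q]``,

which is nonnegative (up to discretization error) because the value under
uncertainty can never exceed the average of best-case values.

*Sample* information is an external datum ``z`` with model-specific law
``P_k(z)`` observed before acting.  Its expected value is computed by
preposterior analysis: average the optimal value over the predictive
distribution of the not-yet-seen datum,

``EVSI = sum_z Pbar(z|q) V[x, q'(z)] - V[x, q]``,

with ``q'(z)`` the Bayes posterior.  An uninformative signal has EVSI zero;
a perfectly informative one recovers EVPI.
"""

from __future__ import annotations

from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .core import (
    DecisionProblem,
    SignalModel,
    ValidationError,
    as_belief,
    signal_marginal,
    update_external,
)
from .dp import ValueSurface, solve_active, solve_known_model, solve_passive
from .grid import BeliefGrid, interpolate_value

__all__ = [
    "evpi_point",
    "evpi_surface",
    "preposterior_value",
    "evsi_external",
    "evsi_surface",
]


def evpi_point(
    problem: DecisionProblem,
    state: int,
    belief: Sequence[float],
    known_values: np.ndarray,
    surface: ValueSurface,
) -> float:
    """EVPI at one (state, belief): ``sum_k q(k) V_k[x] - V[x, q]``.

    ``known_values`` is the ``(K, S)`` stack of single-model optimal values
    from :func:`~amvoi.dp.solve_known_model`; ``surface`` the adaptive value
    surface the comparison is made against.
    """
    q = as_belief(belief, problem.n_models)
    known_values = np.asarray(known_values, dtype=float)
    if known_values.shape != (problem.n_models, problem.n_states):
        raise ValidationError(
            f"known_values shape {known_values.shape} != (K, S)"
        )
    return float(q @ known_values[:, state] - surface.at(state, q))


def evpi_surface(
    problem: DecisionProblem,
    grid: BeliefGrid,
    mode: Literal["active", "passive"] = "active",
    as_percent: bool = False,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """EVPI at every (state, grid belief), as a long-format table.

    Columns: ``state`` (1-based), ``state_label``, one ``q_*`` column per
    model, ``value`` and ``evpi`` (plus ``evpi_percent`` when requested,
    ``100 * EVPI / V``).
    """
    solver = solve_active if mode == "active" else solve_passive
    surface, _ = solver(problem, grid, tol=tol)
    known = np.stack(
        [solve_known_model(problem, k, tol=tol)[0] for k in range(problem.n_models)]
    )  # (K, S)
    V = surface.values  # (S, G)
    evpi = (grid.points @ known).T - V  # (S, G)
    frame = _long_table(problem, grid, {"value": V, "evpi": evpi})
    if as_percent:
        if np.any(V == 0):
            raise ZeroDivisionError(
                "value surface contains zeros; EVPI percent undefined"
            )
        frame["evpi_percent"] = 100.0 * frame["evpi"] / frame["value"]
    frame.attrs.update(surface.metadata)
    return frame


def preposterior_value(
    problem: DecisionProblem,
    state: int,
    belief: Sequence[float],
    signal: SignalModel,
    surface: ValueSurface,
) -> float:
    """Expected optimal value after observing the external signal.

    ``sum_z Pbar(z|q) V[x, q'(z)]`` with ``q'(z)`` the Bayes posterior and
    ``V`` interpolated on the grid; outcomes of zero predictive probability
    contribute nothing.  ``surface`` must come from the solver matching the
    valuation mode (active or passive) being analysed.
    """
    q = as_belief(belief, problem.n_models)
    if signal.n_models != problem.n_models:
        raise ValidationError("signal and problem disagree on the number of models")
    marg = signal_marginal(q, signal)
    total = 0.0
    for z, pz in enumerate(marg):
        if pz <= 0.0:
            continue
        post = update_external(q, signal, z)
        total += pz * surface.at(state, post)
    return float(total)


def evsi_external(
    problem: DecisionProblem,
    state: int,
    belief: Sequence[float],
    signal: SignalModel,
    surface: ValueSurface,
) -> float:
    """EVSI of the external signal at one (state, belief)."""
    q = as_belief(belief, problem.n_models)
    return preposterior_value(problem, state, q, signal, surface) - surface.at(state, q)


def evsi_surface(
    problem: DecisionProblem,
    grid: BeliefGrid,
    signal: SignalModel,
    mode: Literal["active", "passive"] = "active",
    tol: float = 1e-8,
) -> pd.DataFrame:
    """EVSI at every (state, grid belief), as a long-format table.

    Vectorized preposterior sweep: for every outcome ``z`` the posterior of
    every grid belief is interpolated back onto the grid, weighted by the
    predictive probability of ``z`` and accumulated.
    """
    solver = solve_active if mode == "active" else solve_passive
    surface, _ = solver(problem, grid, tol=tol)
    V = surface.values  # (S, G)
    Q = grid.points  # (G, K)
    marg = Q @ signal.distributions  # (G, Z)
    pre = np.zeros_like(V)
    for z in range(signal.n_outcomes):
        pz = marg[:, z]  # (G,)
        lik = signal.distributions[:, z]  # (K,)
        with np.errstate(invalid="ignore", divide="ignore"):
            post = np.where(
                pz[:, None] > 0, Q * lik[None, :] / np.where(pz > 0, pz, 1.0)[:, None], Q
            )
        idx, w = grid.weights(post)
        for x in range(problem.n_states):
            pre[x] += pz * (V[x][idx] * w).sum(axis=1)
    evsi = pre - V
    frame = _long_table(problem, grid, {"value": V, "evsi": evsi})
    frame.attrs.update(surface.metadata)
    frame.attrs["signal_outcomes"] = signal.outcome_labels
    frame.attrs["mode"] = mode
    return frame


def _long_table(
    problem: DecisionProblem, grid: BeliefGrid, columns: dict[str, np.ndarray]
) -> pd.DataFrame:
    S, G = problem.n_states, grid.n_points
    rows = {
        "state": np.repeat(np.arange(1, S + 1), G),
        "state_label": np.repeat(np.asarray(problem.state_labels, dtype=object), G),
    }
    for k in range(grid.n_models):
        rows[f"q_{problem.model_labels[k]}"] = np.tile(grid.points[:, k], S)
    for name, arr in columns.items():
        rows[name] = np.asarray(arr).reshape(S * G)
    return pd.DataFrame(rows)
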