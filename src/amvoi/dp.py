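"""Dynamic-programming solvers over the (system state, belief) space.

Two adaptive-management optimizations are supported:

* **active**: the Bellman backup anticipates learning — the future value is
  evaluated at the Bayes posterior belief implied by each possible next
  state, so the solver will pay for informative (probing) actions;
* **passive**: the future value is evaluated at the *current* belief, so
  learning still happens when the policy is applied but is not anticipated
  during optimization.

Both solve

``V[x, q] = max_a { R(a, x) + lam * sum_x' Pbar(x'|x, a, q) * V[x', q'] }``

with ``q' = posterior(q | x, a, x')`` (active) or ``q' = q`` (passive),
by exact backward induction for finite horizons and by value iteration for
infinite horizons (``lam < 1`` required).  Posterior beliefs are computed
exactly and then mapped through the grid's barycentric interpolation; they
are never snapped to the nearest grid point, which would bias the learning
dynamics.  Successor states of zero probability are skipped: their posterior
is undefined but carries zero weight in the backup.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .core import ConvergenceError, DecisionProblem, ValidationError
from .grid import BeliefGrid

__all__ = [
    "ValueSurface",
    "PolicySurface",
    "solve_active",
    "solve_passive",
    "solve_known_model",
    "evaluate_policy",
]

#: default sup-norm convergence tolerance for value iteration
DEFAULT_TOL = 1e-8
#: default iteration cap for value iteration
DEFAULT_MAX_ITER = 10**6


@dataclass
class ValueSurface:
    """Values ``V[x, g]`` per system state and grid belief point."""

    values: np.ndarray  # (S, G)
    grid: BeliefGrid
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("value surface contains non-finite entries")

    def at(self, state: int, belief) -> float:
        """Interpolated value at an arbitrary belief."""
        from .grid import interpolate_value

        return interpolate_value(self.grid, self.values[state], belief)


@dataclass
class PolicySurface:
    """Optimal in-year action per (state, grid belief).

    For periodic monitoring schedules, :attr:`action_sequences` holds the
    optimal open-loop action sequence ``(a_t, a_{t+1}, ..., a_{t+m-1})`` per
    (state, grid belief) observed at the start of the block; row 0 equals
    :attr:`actions`.  Out-year actions condition only on the last observed
    state, belief and the preceding actions — never on unobserved states.
    """

    actions: np.ndarray  # (S, G) int
    grid: BeliefGrid
    metadata: dict = field(default_factory=dict)
    action_sequences: np.ndarray | None = None  # (m, S, G) int

    def __post_init__(self) -> None:
        self.actions = np.asarray(self.actions, dtype=np.int64)

    @property
    def period(self) -> int:
        return 1 if self.action_sequences is None else self.action_sequences.shape[0]


# ----------------------------------------------------------------------
# backup machinery


class _Backup:
    """Precomputed quantities for repeated Bellman backups on a fixed grid."""

    def __init__(self, problem: DecisionProblem, grid: BeliefGrid):
        if grid.n_models != problem.n_models:
            raise ValidationError(
                f"grid built for {grid.n_models} models, problem has {problem.n_models}"
            )
        self.problem = problem
        self.grid = grid
        P = problem.transitions  # (K, A, S, S)
        Q = grid.points  # (G, K)
        K, A, S, _ = P.shape
        G = grid.n_points
        # model-averaged kernel per grid belief: (A, S, S', G)
        self.pbar = np.einsum("gk,kaxy->axyg", Q, P)
        # exact posterior per (a, x, x', g): (A, S, S', G, K)
        num = Q[None, None, None, :, :] * np.moveaxis(P, 0, -1)[:, :, :, None, :]
        den = self.pbar[..., None]
        with np.errstate(invalid="ignore", divide="ignore"):
            post = np.where(den > 0, num / np.where(den > 0, den, 1.0), Q)
        idx, w = grid.weights(post.reshape(-1, K))
        self.post_idx = idx.reshape(A, S, S, G, K)
        self.post_w = w.reshape(A, S, S, G, K)
        self._ygrid = np.arange(S)[None, None, :, None, None]

    def q_values_active(self, V: np.ndarray) -> np.ndarray:
        """Action values ``Q[a, x, g]`` with anticipated belief updating."""
        p = self.problem
        Vt = ((V[self._ygrid, self.post_idx]) * self.post_w).sum(axis=-1)
        ev = np.einsum("axyg,axyg->axg", self.pbar, Vt)
        return p.rewards[:, :, None] + p.discount * ev

    def q_values_passive(self, V: np.ndarray) -> np.ndarray:
        """Action values ``Q[a, x, g]`` with the belief frozen at the prior."""
        p = self.problem
        ev = np.einsum("axyg,yg->axg", self.pbar, V)
        return p.rewards[:, :, None] + p.discount * ev


def _iterate(
    backup,
    problem: DecisionProblem,
    shape: tuple[int, int],
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, int, float]:
    """Run backward induction (finite T) or value iteration (infinite)."""
    V = np.zeros(shape)
    if problem.finite_horizon:
        T = int(problem.horizon)
        for _ in range(T):
            V = backup(V)
        return V, T, 0.0
    delta = math.inf
    for it in range(1, max_iter + 1):
        Vn = backup(V)
        delta = float(np.max(np.abs(Vn - V)))
        V = Vn
        if delta < tol:
            return V, it, delta
    raise ConvergenceError(
        f"value iteration did not converge: sup-norm change {delta:.3e} after "
        f"{max_iter} iterations (tol {tol:.1e}, discount {problem.discount})"
    )


def _solve(
    problem: DecisionProblem,
    grid: BeliefGrid,
    mode: Literal["active", "passive"],
    tol: float,
    max_iter: int,
) -> tuple[ValueSurface, PolicySurface]:
    ops = _Backup(problem, grid)
    qv = ops.q_values_active if mode == "active" else ops.q_values_passive
    V, its, delta = _iterate(
        lambda V: qv(V).max(axis=0), problem, (problem.n_states, grid.n_points),
        tol, max_iter,
    )
    Q = qv(V)
    # ties broken by lowest action index (np.argmax takes the first maximum)
    policy = Q.argmax(axis=0)
    meta = {
        "mode": mode,
        "discount": problem.discount,
        "horizon": problem.horizon,
        "grid_step": grid.step,
        "tol": tol,
        "iterations": its,
        "final_delta": delta,
        "problem": problem.name,
    }
    return ValueSurface(V, grid, dict(meta)), PolicySurface(policy, grid, dict(meta))


def solve_active(
    problem: DecisionProblem,
    grid: BeliefGrid,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[ValueSurface, PolicySurface]:
    """Optimal active-adaptive value and policy over (state, grid belief)."""
    return _solve(problem, grid, "active", tol, max_iter)


def solve_passive(
    problem: DecisionProblem,
    grid: BeliefGrid,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[ValueSurface, PolicySurface]:
    """Optimal passive-adaptive value and policy (no anticipated learning)."""
    return _solve(problem, grid, "passive", tol, max_iter)


def solve_known_model(
    problem: DecisionProblem,
    model: int,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[np.ndarray, np.ndarray]:
    """Single-model optimal values ``V_k[x]`` and policy.

    Solves the ordinary Markov decision problem with kernel ``P_k``; by
    construction it coincides with the adaptive solution at the degenerate
    belief ``e_k`` (a grid vertex, so no interpolation error is involved).
    """
    if not 0 <= model < problem.n_models:
        raise ValidationError(f"model index {model} out of range")
    P = problem.transitions[model]  # (A, S, S)
    R = problem.rewards
    lam = problem.discount

    def backup(V: np.ndarray) -> np.ndarray:
        return (R + lam * np.einsum("axy,y->ax", P, V)).max(axis=0)

    V, _, _ = _iterate(backup, problem, (problem.n_states,), tol, max_iter)
    policy = (R + lam * np.einsum("axy,y->ax", P, V)).argmax(axis=0)
    return V, policy


def evaluate_policy(
    problem: DecisionProblem,
    policy: PolicySurface | np.ndarray,
    grid: BeliefGrid,
    updating: Literal["internal", "none"] = "internal",
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> ValueSurface:
    """Expected cumulative return of a fixed stationary policy.

    Under ``updating="internal"`` the manager's belief follows the Bayes
    posterior of each observed transition (the true learning dynamics); under
    ``"none"`` the belief is frozen, so the policy is replayed at the prior
    belief forever.  Either way the policy itself is fixed — this is policy
    evaluation, not optimization.
    """
    if updating not in ("internal", "none"):
        raise ValidationError(f"unknown updating mode {updating!r}")
    actions = policy.actions if isinstance(policy, PolicySurface) else np.asarray(policy)
    S, G = problem.n_states, grid.n_points
    if actions.shape != (S, G):
        raise ValidationError(f"policy shape {actions.shape} != ({S}, {G})")
    if actions.min() < 0 or actions.max() >= problem.n_actions:
        raise ValidationError("policy contains out-of-range action indices")
    ops = _Backup(problem, grid)
    qv = ops.q_values_active if updating == "internal" else ops.q_values_passive
    xi = np.arange(S)[:, None]
    gi = np.arange(G)[None, :]

    V, its, delta = _iterate(
        lambda V: qv(V)[actions, xi, gi], problem, (S, G), tol, max_iter
    )
    meta = {
        "mode": f"evaluate/{updating}",
        "discount": problem.discount,
        "horizon": problem.horizon,
        "grid_step": grid.step,
        "tol": tol,
        "iterations": its,
        "final_delta": delta,
        "problem": problem.name,
    }
    return ValueSurface(V, grid, meta)
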