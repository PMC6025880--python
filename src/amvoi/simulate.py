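"""Forward Monte-Carlo simulation of managed trajectories.

A "true" model is fixed (or drawn from the prior), states evolve by its
kernel, the manager follows a solved policy, and the manager's belief is
updated by Bayes' rule at observation years only.  Under a periodic
monitoring schedule (period ``m > 1``) the belief is carried forward
unchanged through out-years and, at the next observation, all intervening
observed transitions are folded in sequentially; out-year actions come from
the periodic policy's committed action sequence.

Because policies are defined on grid beliefs, the manager's (generally
off-grid) belief is mapped to the highest-weight vertex of its containing
grid simplex when an action is looked up; the belief itself is never
snapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    DecisionProblem,
    ImpossibleObservationError,
    ValidationError,
)
from .dp import PolicySurface
from .grid import BeliefGrid

__all__ = ["Trajectory", "simulate_trajectory", "compare_schemes", "plot_trajectory"]


@dataclass
class Trajectory:
    """One realized management trajectory."""

    states: np.ndarray  # (T+1,) visited states
    actions: np.ndarray  # (T,) actions taken
    rewards: np.ndarray  # (T,) undiscounted per-step returns
    beliefs: np.ndarray  # (T+1, K) manager's belief before acting at each time
    observed: np.ndarray  # (T+1,) bool, monitoring year?
    discount: float
    true_model: int

    @property
    def total_return(self) -> float:
        """Discounted cumulative return."""
        T = self.rewards.size
        return float(self.rewards @ self.discount ** np.arange(T))

    def to_frame(self) -> pd.DataFrame:
        T = self.actions.size
        return pd.DataFrame(
            {
                "time": np.arange(T),
                "state": self.states[:T],
                "action": self.actions,
                "reward": self.rewards,
                "observed": self.observed[:T],
                **{
                    f"q_{k}": self.beliefs[:T, k]
                    for k in range(self.beliefs.shape[1])
                },
            }
        )


def _policy_lookup(grid: BeliefGrid, q: np.ndarray) -> int:
    if grid.n_models == 2:
        # lattice index of the nearest vertex: points ordered by ascending q[0]
        return int(round(q[0] * grid.n_subdivisions))
    idx, w = grid.weights(q[None, :])
    return int(idx[0, int(np.argmax(w[0]))])


def simulate_trajectory(
    problem: DecisionProblem,
    policy: PolicySurface,
    true_model: int,
    horizon: int,
    seed: int | np.random.Generator,
    period: int = 1,
    initial_state: int = 0,
    initial_belief: Sequence[float] | None = None,
) -> Trajectory:
    """Simulate one trajectory under a chosen true model.

    ``policy`` must be an annual policy for ``period = 1`` or a periodic
    policy (with committed out-year action sequences) whose period matches.
    """
    if period != policy.period:
        raise ValidationError(
            f"policy has period {policy.period}, schedule requested {period}"
        )
    if not 0 <= true_model < problem.n_models:
        raise ValidationError(f"true model index {true_model} out of range")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    K, S = problem.n_models, problem.n_states
    q = (
        np.full(K, 1.0 / K)
        if initial_belief is None
        else np.asarray(initial_belief, dtype=float)
    )
    grid = policy.grid
    Pk = problem.transitions[true_model]  # (A, S, S)

    cum = np.cumsum(Pk, axis=-1)  # inverse-CDF sampling beats rng.choice here
    P_all = problem.transitions  # (K, A, S, S)

    states = np.empty(horizon + 1, dtype=np.int64)
    actions = np.empty(horizon, dtype=np.int64)
    rewards = np.empty(horizon)
    beliefs = np.empty((horizon + 1, K))
    observed = np.zeros(horizon + 1, dtype=bool)
    states[0] = initial_state
    x = initial_state
    pending: list[tuple[int, int, int]] = []  # unprocessed (x, a, x') transitions
    seq = None
    for t in range(horizon):
        j = t % period
        if j == 0:  # observation year
            for (xs, as_, xn) in pending:
                lik = P_all[:, as_, xs, xn]
                marginal = q @ lik
                if marginal <= 0.0:
                    raise ImpossibleObservationError(
                        f"transition {xs}->{xn} under action {as_} has zero "
                        f"probability under belief {q}"
                    )
                q = q * lik / marginal
            pending = []
            observed[t] = True
            g = _policy_lookup(grid, q)
            if policy.action_sequences is not None:
                seq = policy.action_sequences[:, x, g]
                a = int(seq[0])
            else:
                a = int(policy.actions[x, g])
        else:  # out-year: committed action, no belief update
            if seq is None:
                raise ValidationError("out-year reached but policy has no sequences")
            a = int(seq[j])
        beliefs[t] = q
        actions[t] = a
        rewards[t] = problem.rewards[a, x]
        x_next = int(np.searchsorted(cum[a, x], rng.random(), side="right"))
        x_next = min(x_next, S - 1)
        pending.append((x, a, x_next))
        states[t + 1] = x_next
        x = x_next
    beliefs[horizon] = q
    observed[horizon] = horizon % period == 0
    return Trajectory(
        states=states,
        actions=actions,
        rewards=rewards,
        beliefs=beliefs,
        observed=observed,
        discount=problem.discount,
        true_model=true_model,
    )


def compare_schemes(
    problem: DecisionProblem,
    policies: dict[int, PolicySurface],
    horizon: int,
    replicates: int,
    seed: int,
    true_models: Sequence[int] | None = None,
    initial_state: int = 0,
    initial_belief: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Monte-Carlo comparison of monitoring schedules.

    ``policies`` maps each monitoring period to its solved policy (annual
    policies for ``1``, periodic for ``m > 1``).  For each schedule and each
    true model, ``replicates`` trajectories are simulated and the mean
    cumulative return, its Monte-Carlo standard error and the mean final
    belief in the true model are reported.  One master seed spawns one
    deterministic stream per (schedule, model, replicate).
    """
    if true_models is None:
        true_models = list(range(problem.n_models))
    rows = []
    master = np.random.SeedSequence(seed)
    streams = master.spawn(len(policies) * len(true_models))
    i = 0
    for period in sorted(policies):
        policy = policies[period]
        for k in true_models:
            child = streams[i]
            i += 1
            returns = np.empty(replicates)
            final_q = np.empty(replicates)
            for r, ss in enumerate(child.spawn(replicates)):
                traj = simulate_trajectory(
                    problem,
                    policy,
                    true_model=k,
                    horizon=horizon,
                    seed=np.random.default_rng(ss),
                    period=period,
                    initial_state=initial_state,
                    initial_belief=initial_belief,
                )
                returns[r] = traj.total_return
                final_q[r] = traj.beliefs[-1, k]
            rows.append(
                {
                    "period": period,
                    "true_model": problem.model_labels[k],
                    "replicates": replicates,
                    "mean_return": returns.mean(),
                    "se_return": returns.std(ddof=1) / np.sqrt(replicates)
                    if replicates > 1
                    else 0.0,
                    "mean_final_q_true": final_q.mean(),
                }
            )
    frame = pd.DataFrame(rows)
    frame.attrs = {
        "problem": problem.name,
        "horizon": horizon,
        "seed": seed,
        "initial_state": initial_state,
    }
    return frame


def plot_trajectory(trajectory: Trajectory, ax=None):
    """Line plot of state occupancy and belief against time (optional hook)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    T = trajectory.actions.size
    ax.step(np.arange(T + 1), trajectory.states, where="post", label="state")
    ax2 = ax.twinx()
    ax2.plot(np.arange(T + 1), trajectory.beliefs[:, 0], "C1", label="q(model 0)")
    ax2.set_ylim(-0.02, 1.02)
    ax.set_xlabel("time")
    ax.set_ylabel("state index")
    ax2.set_ylabel("belief in model 0")
    return ax
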