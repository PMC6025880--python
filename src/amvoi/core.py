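"""Core domain types and Bayesian belief machinery.

A managed resource is modelled as a finite Markov decision process whose
transition structure is uncertain: ``K`` rival models (hypotheses) each supply
a full transition kernel ``P_k(x' | x, a)``.  Uncertainty about which model
best represents the system is carried as a *belief* (model state) ``q``, a
probability vector over the models, updated by Bayes' theorem as transitions
are observed (internal information) or as external data arrive.

Beliefs are plain length-``K`` numpy arrays; :func:`as_belief` validates them.
All probability rows must sum to one within ``PROB_TOL``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PROB_TOL",
    "AmvoiError",
    "ValidationError",
    "ImpossibleObservationError",
    "ConvergenceError",
    "FixtureUnavailableError",
    "DecisionProblem",
    "SignalModel",
    "as_belief",
    "validate_problem",
    "model_averaged_transition",
    "update_internal",
    "update_external",
    "signal_marginal",
]

#: Tolerance on probability normalisation of input rows and beliefs.
PROB_TOL = 1e-10


class AmvoiError(Exception):
    """Base class for errors raised by this package."""


class ValidationError(AmvoiError):
    """A problem, belief or signal model violates a structural invariant."""


class ImpossibleObservationError(AmvoiError):
    """Bayes update conditioned on an observation of zero marginal probability."""


class ConvergenceError(AmvoiError):
    """An iterative solver failed to converge within its iteration cap."""


class FixtureUnavailableError(AmvoiError):
    """A packaged data fixture is missing or corrupt."""


@dataclass(frozen=True)
class DecisionProblem:
    """A structurally uncertain Markov decision problem.

    Parameters
    ----------
    state_labels, action_labels, model_labels
        Ordered labels for the ``S`` system states, ``A`` actions and ``K``
        candidate transition models.
    transitions
        Array of shape ``(K, A, S, S)``; ``transitions[k, a, x, y]`` is
        ``P_k(y | x, a)``.  Every row (fixed ``k, a, x``) must be a
        probability distribution.
    rewards
        Array of shape ``(A, S)``; ``rewards[a, x]`` is the return
        ``R(a, x)`` earned by taking action ``a`` in state ``x`` (benefits
        net of action costs).
    discount
        Per-step discount factor ``lambda`` in ``(0, 1]``.
    horizon
        Number of decision stages ``T`` (a positive integer) or
        ``math.inf`` for an infinite horizon, which requires ``discount < 1``.
    """

    state_labels: tuple[str, ...]
    action_labels: tuple[str, ...]
    model_labels: tuple[str, ...]
    transitions: np.ndarray
    rewards: np.ndarray
    discount: float = 1.0
    horizon: float = math.inf
    name: str = "problem"

    def __post_init__(self) -> None:
        object.__setattr__(self, "state_labels", tuple(self.state_labels))
        object.__setattr__(self, "action_labels", tuple(self.action_labels))
        object.__setattr__(self, "model_labels", tuple(self.model_labels))
        object.__setattr__(
            self, "transitions", np.asarray(self.transitions, dtype=float)
        )
        object.__setattr__(self, "rewards", np.asarray(self.rewards, dtype=float))
        violations = validate_problem(self)
        structural = [v for v in violations if v.startswith("structure:")]
        if structural:
            raise ValidationError("; ".join(structural))
        if violations:
            raise ValidationError("; ".join(violations))

    # -- convenience ---------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    @property
    def n_actions(self) -> int:
        return len(self.action_labels)

    @property
    def n_models(self) -> int:
        return len(self.model_labels)

    @property
    def finite_horizon(self) -> bool:
        return math.isfinite(self.horizon)

    def replace(self, **kwargs) -> "DecisionProblem":
        """Return a copy with the given fields replaced."""
        data = {
            "state_labels": self.state_labels,
            "action_labels": self.action_labels,
            "model_labels": self.model_labels,
            "transitions": self.transitions,
            "rewards": self.rewards,
            "discount": self.discount,
            "horizon": self.horizon,
            "name": self.name,
        }
        data.update(kwargs)
        return DecisionProblem(**data)


@dataclass(frozen=True)
class SignalModel:
    """Finite-alphabet external data source with per-model outcome laws.

    ``distributions[k, z]`` is the probability ``P_k(z)`` that an external
    investigation returns outcome ``z`` if model ``k`` is the true one.
    The signal is what a preposterior analysis averages over: before the
    datum is seen, outcome ``z`` has marginal probability
    ``sum_k q(k) P_k(z)`` under belief ``q``.
    """

    outcome_labels: tuple[str, ...]
    distributions: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "outcome_labels", tuple(self.outcome_labels))
        dists = np.asarray(self.distributions, dtype=float)
        object.__setattr__(self, "distributions", dists)
        if dists.ndim != 2 or dists.shape[1] != len(self.outcome_labels):
            raise ValidationError(
                "structure: signal distributions must have shape (K, Z) "
                f"matching {len(self.outcome_labels)} outcomes, got {dists.shape}"
            )
        if not np.all(np.isfinite(dists)) or np.any(dists < 0):
            raise ValidationError("signal distributions must be finite and nonnegative")
        sums = dists.sum(axis=1)
        bad = np.nonzero(np.abs(sums - 1.0) > PROB_TOL)[0]
        if bad.size:
            raise ValidationError(
                f"signal distribution for model(s) {bad.tolist()} does not sum to 1"
            )

    @property
    def n_models(self) -> int:
        return self.distributions.shape[0]

    @property
    def n_outcomes(self) -> int:
        return self.distributions.shape[1]


def as_belief(q: Sequence[float], n_models: int | None = None) -> np.ndarray:
    """Validate and return a belief vector as a float array.

    Raises :class:`ValidationError` if ``q`` is not a probability vector
    (nonnegative, summing to one within ``PROB_TOL``) of the expected length.
    """
    arr = np.asarray(q, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"belief must be a vector, got shape {arr.shape}")
    if n_models is not None and arr.size != n_models:
        raise ValidationError(f"belief has length {arr.size}, expected {n_models}")
    if not np.all(np.isfinite(arr)) or np.any(arr < 0):
        raise ValidationError("belief entries must be finite and nonnegative")
    if abs(arr.sum() - 1.0) > PROB_TOL:
        raise ValidationError(f"belief sums to {arr.sum():.12g}, not 1")
    return arr


def validate_problem(problem: DecisionProblem) -> list[str]:
    """Check every structural invariant of a decision problem.

    Returns a list of human-readable violation strings; an empty list means
    the problem is valid.  Malformed array dimensions are reported with a
    ``structure:`` prefix, distinguishing them from probability-sum
    violations, which name the offending ``(model, action, state)`` row.
    """
    report: list[str] = []
    S, A, K = problem.n_states, problem.n_actions, problem.n_models
    if S < 1 or A < 1 or K < 1:
        report.append("structure: need at least one state, action and model")
        return report
    P, R = problem.transitions, problem.rewards
    if P.ndim != 4 or P.shape != (K, A, S, S):
        report.append(
            f"structure: transitions shape {P.shape} != (K={K}, A={A}, S={S}, S={S})"
        )
        return report
    if R.shape != (A, S):
        report.append(f"structure: rewards shape {R.shape} != (A={A}, S={S})")
        return report

    if not np.all(np.isfinite(R)):
        report.append("rewards contain non-finite entries")
    if not np.all(np.isfinite(P)):
        report.append("transitions contain non-finite entries")
    else:
        neg = np.argwhere(P < 0)
        for k, a, x, y in neg[:5]:
            report.append(
                f"negative transition probability at (model={k}, action={a}, "
                f"state={x}, next={y})"
            )
        sums = P.sum(axis=3)
        bad = np.argwhere(np.abs(sums - 1.0) > PROB_TOL)
        for k, a, x in bad[:20]:
            report.append(
                f"transition row (model={k}, action={a}, state={x}) sums to "
                f"{sums[k, a, x]:.12g}, not 1"
            )
    if not (0.0 < problem.discount <= 1.0):
        report.append(f"discount {problem.discount} outside (0, 1]")
    if math.isinf(problem.horizon):
        if problem.discount >= 1.0:
            report.append("infinite horizon requires discount < 1")
    elif not (float(problem.horizon).is_integer() and problem.horizon >= 1):
        report.append(f"horizon must be a positive integer or inf, got {problem.horizon}")
    return report


def model_averaged_transition(
    problem: DecisionProblem, belief: Sequence[float], action: int
) -> np.ndarray:
    """Belief-weighted mixture kernel ``sum_k q(k) P_k(. | ., a)``.

    Returns the ``(S, S)`` model-averaged transition matrix for ``action``;
    rows are probability distributions because the mixture of distributions
    with convex weights is a distribution.
    """
    q = as_belief(belief, problem.n_models)
    return np.einsum("k,kxy->xy", q, problem.transitions[:, action])


def update_internal(
    problem: DecisionProblem,
    belief: Sequence[float],
    state: int,
    action: int,
    next_state: int,
) -> np.ndarray:
    """Bayes update of the model state from an observed transition.

    ``q'(k) = q(k) P_k(x' | x, a) / sum_j q(j) P_j(x' | x, a)``.
    Raises :class:`ImpossibleObservationError` if the observed transition has
    zero probability under every model with positive prior weight.
    """
    q = as_belief(belief, problem.n_models)
    lik = problem.transitions[:, action, state, next_state]
    return _bayes(q, lik, what=f"transition {state}->{next_state} under action {action}")


def update_external(
    belief: Sequence[float], signal: SignalModel, outcome: int
) -> np.ndarray:
    """Bayes update of the model state from an external datum ``z``.

    ``q'(k) = q(k) P_k(z) / sum_j q(j) P_j(z)``.
    """
    q = as_belief(belief, signal.n_models)
    lik = signal.distributions[:, outcome]
    return _bayes(q, lik, what=f"external outcome {outcome}")


def signal_marginal(belief: Sequence[float], signal: SignalModel) -> np.ndarray:
    """Predictive distribution of the external datum: ``sum_k q(k) P_k(z)``."""
    q = as_belief(belief, signal.n_models)
    return q @ signal.distributions


def _bayes(q: np.ndarray, likelihood: np.ndarray, what: str) -> np.ndarray:
    marginal = float(q @ likelihood)
    if marginal <= 0.0:
        raise ImpossibleObservationError(
            f"observed {what} has zero marginal probability under belief {q}"
        )
    return q * likelihood / marginal
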