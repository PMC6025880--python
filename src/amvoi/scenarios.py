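"""Packaged scenarios and random test-problem generators.

The motivating application is prescribed-fire management of Florida scrub
for scrub-jay habitat: five height/openness classes of scrub (short-open,
short-closed, optimal-open, optimal-closed, tall-mix), three actions
(do nothing, routine burn, intensive burn) and two rival transition models —
a *null* model under which routine and intensive burns are equally effective
at setting back succession (so the dearer intensive burn is never optimal),
and an *alternative* model under which the intensive burn sets succession
back harder in the fire-resistant classes.

The published per-class transition probabilities and returns live in the
original study's supplementary material, which is not redistributed here;
:func:`load_scrubjay` loads a user-supplied transcription of it.
:func:`load_scrubjay_synthetic` loads a clearly-labelled synthetic stand-in
with the same qualitative structure, packaged so that every part of the
library is exercisable without external data.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np

from .core import DecisionProblem, FixtureUnavailableError, SignalModel, ValidationError

__all__ = [
    "load_scrubjay",
    "load_scrubjay_synthetic",
    "random_problem",
    "random_signal_model",
]

_TRANSCRIPTION_HELP = (
    "the transcription must be a problem-spec YAML file (see amvoi.specio) with "
    "5 states (short-open, short-closed, optimal-open, optimal-closed, tall-mix), "
    "3 actions (do-nothing, routine-burn, intensive-burn) and 2 models (null, "
    "alternative), each model giving one 5x5 one-year transition matrix per "
    "action, plus per-action/state returns net of burn cost, copied from the "
    "original study's supplementary file of scrub transition probabilities "
    "and returns"
)


def _load_fixture(filename: str):
    from .specio import read_problem_spec

    ref = resources.files("amvoi.data").joinpath(filename)
    if not ref.is_file():
        raise FixtureUnavailableError(
            f"packaged fixture {filename!r} is missing; {_TRANSCRIPTION_HELP}"
        )
    with resources.as_file(ref) as path:
        return read_problem_spec(path)


def load_scrubjay():
    """Load the transcribed Florida scrub-jay problem (if packaged).

    Returns ``(problem, signal, period)``; model 0 is the null model, so a
    two-entry belief's first coordinate is the probability of the null model.

    The transcription of the published transition probabilities and returns
    is not distributable with this package; until a `scrubjay.yaml`
    transcription is placed in ``amvoi/data/``, this raises
    :class:`FixtureUnavailableError` with instructions rather than guessing
    values.  Use :func:`load_scrubjay_synthetic` for a structurally faithful
    synthetic stand-in.
    """
    return _load_fixture("scrubjay.yaml")


def load_scrubjay_synthetic():
    """Load the *synthetic* scrub-jay-style fixture.

    The numbers are constructed, not the published estimates: succession
    advances under do-nothing, burns set vegetation back (open classes
    respond well, closed/tall classes resist), the null model's routine and
    intensive burn kernels are identical, and the alternative model's
    intensive burn is markedly more effective in the fire-resistant classes.
    Returns drop with distance from optimal-height scrub and are charged the
    burn cost, the intensive burn costing more.  Returns
    ``(problem, signal, period)`` with model 0 the null model; the packaged
    signal is the one-year response of an external short-closed unit to an
    intensive burn.
    """
    return _load_fixture("scrubjay_synthetic.yaml")


def random_problem(
    n_states: int,
    n_actions: int,
    n_models: int,
    seed: int,
    concentration: float = 1.0,
    reward_range: tuple[float, float] = (0.0, 1.0),
    discount: float = 0.95,
    horizon: float = float("inf"),
) -> DecisionProblem:
    """Random decision problem with Dirichlet transition rows.

    Every transition row is drawn from a symmetric Dirichlet with the given
    ``concentration`` (large values approach uniform rows); rewards are
    uniform on ``reward_range``.  Fully reproducible per ``seed``.
    """
    if min(n_states, n_actions, n_models) < 1:
        raise ValidationError("need at least one state, action and model")
    rng = np.random.default_rng(seed)
    P = rng.dirichlet(
        np.full(n_states, concentration), size=(n_models, n_actions, n_states)
    )
    R = rng.uniform(*reward_range, size=(n_actions, n_states))
    return DecisionProblem(
        state_labels=tuple(f"s{i}" for i in range(n_states)),
        action_labels=tuple(f"a{i}" for i in range(n_actions)),
        model_labels=tuple(f"m{i}" for i in range(n_models)),
        transitions=P,
        rewards=R,
        discount=discount,
        horizon=horizon,
        name=f"random-{seed}",
    )


def random_signal_model(
    n_models: int,
    n_outcomes: int,
    seed: int,
    informativeness: float = 0.5,
) -> SignalModel:
    """Random external-signal model with tunable informativeness.

    ``informativeness = 0`` gives every model the same outcome law (the
    signal carries no model information); ``informativeness = 1`` gives each
    model all of its mass on its own disjoint outcome block (one observation
    identifies the model), which requires ``n_outcomes >= n_models``;
    intermediate values blend the two convexly.
    """
    if not 0.0 <= informativeness <= 1.0:
        raise ValidationError("informativeness must lie in [0, 1]")
    if informativeness == 1.0 and n_outcomes < n_models:
        raise ValidationError(
            "perfect informativeness requires at least as many outcomes as models"
        )
    rng = np.random.default_rng(seed)
    shared = rng.dirichlet(np.ones(n_outcomes))
    dists = np.tile(shared, (n_models, 1))
    if informativeness > 0.0:
        if n_outcomes < n_models:
            raise ValidationError(
                "informative signals require at least as many outcomes as models"
            )
        exclusive = np.zeros((n_models, n_outcomes))
        blocks = [
            [z for z in range(n_outcomes) if z % n_models == k] for k in range(n_models)
        ]
        for k, block in enumerate(blocks):
            mass = rng.dirichlet(np.ones(len(block)))
            exclusive[k, block] = mass
        dists = (1.0 - informativeness) * dists + informativeness * exclusive
    return SignalModel(
        outcome_labels=tuple(f"z{i}" for i in range(n_outcomes)),
        distributions=dists,
    )
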