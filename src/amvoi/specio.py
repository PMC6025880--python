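"""Problem-spec file format and result-table writers.

A problem spec is a single human-readable YAML file: label orders are
declared once, matrices are lists of rows indexed action-major then state,
so a transcription from a printed table can be audited line by line.

Schema (``?`` marks optional keys)::

    name: <str>?
    states: [<label>, ...]
    actions: [<label>, ...]
    models: [<label>, ...]
    discount: <float>           # in (0, 1]
    horizon: <int> | infinite
    rewards:                    # one row of S returns per action
      <action label>: [<float> x S]
    transitions:
      <model label>:
        <action label>:
          - [<float> x S]       # one row per current state
    signal:?                    # external-data source
      outcomes: [<label>, ...]
      distributions:
        <model label>: [<float> x Z]
    monitoring_period: <int>?   # years between observations

Result tables are written as delimited text with ``#``-prefixed metadata
header lines echoing every parameter needed to re-run the computation.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .core import DecisionProblem, SignalModel, ValidationError

__all__ = [
    "read_problem_spec",
    "write_problem_spec",
    "write_results",
    "read_results",
]

_RESULT_KINDS = ("value", "policy", "voi", "monitoring", "trajectory")


def _require(mapping: dict, key: str, where: str) -> Any:
    if not isinstance(mapping, dict) or key not in mapping:
        raise ValidationError(f"problem spec is missing key {where}{key!r}")
    return mapping[key]


def read_problem_spec(
    path: str | Path,
) -> tuple[DecisionProblem, SignalModel | None, int | None]:
    """Read and validate a problem-spec file.

    Returns ``(problem, signal, monitoring_period)``; the latter two are
    ``None`` when absent from the file.  Schema violations are reported with
    the offending key path; probability-sum violations name the
    (model, action, state) row.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValidationError(f"{path} does not contain a mapping at top level")

    states = [str(s) for s in _require(raw, "states", "")]
    actions = [str(a) for a in _require(raw, "actions", "")]
    models = [str(m) for m in _require(raw, "models", "")]
    S = len(states)

    rewards_raw = _require(raw, "rewards", "")
    R = np.empty((len(actions), S))
    for i, a in enumerate(actions):
        row = _require(rewards_raw, a, "rewards/")
        if len(row) != S:
            raise ValidationError(
                f"rewards/{a!r} has {len(row)} entries, expected {S}"
            )
        R[i] = row

    trans_raw = _require(raw, "transitions", "")
    P = np.empty((len(models), len(actions), S, S))
    for k, m in enumerate(models):
        per_model = _require(trans_raw, m, "transitions/")
        for i, a in enumerate(actions):
            mat = _require(per_model, a, f"transitions/{m}/")
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (S, S):
                raise ValidationError(
                    f"transitions/{m}/{a} has shape {mat.shape}, expected ({S}, {S})"
                )
            P[k, i] = mat

    horizon_raw = raw.get("horizon", "infinite")
    if isinstance(horizon_raw, str):
        if horizon_raw.lower() not in ("inf", "infinite"):
            raise ValidationError(f"horizon {horizon_raw!r} not understood")
        horizon: float = math.inf
    else:
        horizon = float(horizon_raw)

    problem = DecisionProblem(
        state_labels=states,
        action_labels=actions,
        model_labels=models,
        transitions=P,
        rewards=R,
        discount=float(raw.get("discount", 1.0)),
        horizon=horizon,
        name=str(raw.get("name", path.stem)),
    )

    signal = None
    if "signal" in raw and raw["signal"] is not None:
        sig_raw = raw["signal"]
        outcomes = [str(z) for z in _require(sig_raw, "outcomes", "signal/")]
        dist_raw = _require(sig_raw, "distributions", "signal/")
        D = np.empty((len(models), len(outcomes)))
        for k, m in enumerate(models):
            row = _require(dist_raw, m, "signal/distributions/")
            if len(row) != len(outcomes):
                raise ValidationError(
                    f"signal/distributions/{m} has {len(row)} entries, "
                    f"expected {len(outcomes)}"
                )
            D[k] = row
        signal = SignalModel(outcome_labels=outcomes, distributions=D)

    period = raw.get("monitoring_period")
    if period is not None:
        period = int(period)
        if period < 1:
            raise ValidationError("monitoring_period must be >= 1")
    return problem, signal, period


def write_problem_spec(
    problem: DecisionProblem,
    path: str | Path,
    signal: SignalModel | None = None,
    monitoring_period: int | None = None,
) -> None:
    """Write a problem spec; re-reading reproduces the arrays bit-exactly."""
    doc: dict[str, Any] = {
        "name": problem.name,
        "states": list(problem.state_labels),
        "actions": list(problem.action_labels),
        "models": list(problem.model_labels),
        "discount": float(problem.discount),
        "horizon": "infinite" if not problem.finite_horizon else int(problem.horizon),
        "rewards": {
            a: [float(v) for v in problem.rewards[i]]
            for i, a in enumerate(problem.action_labels)
        },
        "transitions": {
            m: {
                a: [[float(v) for v in row] for row in problem.transitions[k, i]]
                for i, a in enumerate(problem.action_labels)
            }
            for k, m in enumerate(problem.model_labels)
        },
    }
    if signal is not None:
        doc["signal"] = {
            "outcomes": list(signal.outcome_labels),
            "distributions": {
                m: [float(v) for v in signal.distributions[k]]
                for k, m in enumerate(problem.model_labels)
            },
        }
    if monitoring_period is not None:
        doc["monitoring_period"] = int(monitoring_period)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def write_results(
    frame: pd.DataFrame, path: str | Path, kind: str, metadata: dict | None = None
) -> None:
    """Write a result table as TSV with a commented metadata header.

    ``kind`` is one of ``value``, ``policy``, ``voi``, ``monitoring``,
    ``trajectory`` and is recorded in the header together with ``metadata``
    (typically the solver metadata: mode, discount, horizon, grid step,
    tolerance, seed) so the exact computation can be re-run.
    """
    if kind not in _RESULT_KINDS:
        raise ValidationError(f"unknown result kind {kind!r}; expected {_RESULT_KINDS}")
    meta = {"kind": kind}
    meta.update(getattr(frame, "attrs", {}) or {})
    meta.update(metadata or {})
    with open(path, "w") as fh:
        for key in sorted(meta):
            fh.write(f"# {key}: {meta[key]}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a table written by :func:`write_results` (header in ``attrs``)."""
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines:
        if not line.startswith("#"):
            break
        key, _, value = line[1:].strip().partition(": ")
        meta[key] = value
    frame = pd.read_csv(path, sep="\t", comment="#")
    frame.attrs = meta
    return frame
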