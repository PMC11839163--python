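"""Cued-turning-task (CTTT) session scoring.

Trial timeline: a 2-s tone or light cue, treadmill stop 1 s after cue offset,
a 5-s pause, then restart (reversed direction after a turn cue).  Scoring
applies only the timing rules to logged turn/stop events — the 90-degree
body-rotation judgment behind a logged turn is an input, not computed here.

Outcomes:

* turn trial  -> ``cued_turn`` iff a turn was initiated within 8 s of cue
  onset (boundary inclusive), else ``miss``;
* stop trial  -> ``false_turn`` iff a turn occurred during the 5-s pause,
  else ``cued_stop`` when a stop was observed; stop trials with neither event
  are emitted as ``unclassified`` rather than guessed.

The learning criterion is >= 70% correct responses to both cue types on two
consecutive sessions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TrialOutcome",
    "SessionSummary",
    "TURN_DEADLINE_S",
    "CRITERION_RATIO",
    "score_trial",
    "score_session",
    "summarize_session",
    "criterion_reached",
]

CUE_DURATION_S = 2.0
TREADMILL_STOP_S = 3.0   # after cue onset
PAUSE_END_S = 8.0        # after cue onset
TURN_DEADLINE_S = 8.0    # turn must be initiated within 8 s of cue onset
CRITERION_RATIO = 0.70
CRITERION_CONSECUTIVE = 2


@dataclass(frozen=True)
class TrialOutcome:
    outcome: str                      # cued_turn|miss|cued_stop|false_turn|unclassified
    initiation_latency: float | None  # s from cue onset
    completion_latency: float | None


@dataclass(frozen=True)
class SessionSummary:
    turn_ratio: float | None      # turns / turn-cue trials
    stop_ratio: float | None      # stops / stop-cue trials
    n_turn_trials: int
    n_stop_trials: int
    mean_initiation_s: float | None
    mean_completion_s: float | None
    mean_turn_duration_s: float | None


def _finite(x) -> bool:
    try:
        return x is not None and math.isfinite(float(x))
    except (TypeError, ValueError):
        return False


def score_trial(cue_role: str, cue_onset: float,
                turn_initiation: float | None = None,
                turn_completion: float | None = None,
                stop_observed: bool = False) -> TrialOutcome:
    """Score one trial from its cue role and logged event times (absolute s)."""
    if cue_role not in ("turn", "stop"):
        raise ValueError(f"cue_role must be 'turn' or 'stop', got {cue_role!r}")
    has_turn = _finite(turn_initiation)
    init_lat = float(turn_initiation) - cue_onset if has_turn else None
    comp_lat = (float(turn_completion) - cue_onset
                if _finite(turn_completion) else None)
    if comp_lat is not None and init_lat is not None and comp_lat < init_lat:
        raise ValueError("turn completion precedes initiation")
    if comp_lat is not None and init_lat is None:
        raise ValueError("turn completion without initiation")

    if cue_role == "turn":
        if has_turn and init_lat <= TURN_DEADLINE_S:
            return TrialOutcome("cued_turn", init_lat, comp_lat)
        return TrialOutcome("miss", init_lat, comp_lat)
    # stop trial: a turn during the pause is a false turn
    if has_turn and TREADMILL_STOP_S <= init_lat <= PAUSE_END_S:
        return TrialOutcome("false_turn", init_lat, comp_lat)
    if stop_observed:
        return TrialOutcome("cued_stop", None, None)
    return TrialOutcome("unclassified", init_lat, comp_lat)


def score_session(events: pd.DataFrame) -> pd.DataFrame:
    """Score every trial of an event-log frame; returns outcomes table."""
    rows = []
    for row in events.itertuples():
        res = score_trial(
            cue_role=row.role, cue_onset=row.cue_onset_s,
            turn_initiation=getattr(row, "turn_init_s", None),
            turn_completion=getattr(row, "turn_complete_s", None),
            stop_observed=bool(getattr(row, "stop_observed", False)))
        rows.append({
            "trial": row.trial, "role": row.role,
            "outcome": res.outcome,
            "initiation_latency_s": res.initiation_latency,
            "completion_latency_s": res.completion_latency,
        })
    return pd.DataFrame(rows)


def summarize_session(outcomes: pd.DataFrame) -> SessionSummary:
    """Session ratios and turn-timing means from a scored-outcomes table."""
    turn_trials = outcomes[outcomes["role"] == "turn"]
    stop_trials = outcomes[outcomes["role"] == "stop"]
    if len(turn_trials) == 0 and len(stop_trials) == 0:
        raise ValueError("session has no trials")

    turn_ratio = (float((turn_trials["outcome"] == "cued_turn").mean())
                  if len(turn_trials) else None)
    stop_ratio = (float((stop_trials["outcome"] == "cued_stop").mean())
                  if len(stop_trials) else None)

    turns = turn_trials[turn_trials["outcome"] == "cued_turn"]
    init = turns["initiation_latency_s"].dropna()
    comp = turns["completion_latency_s"].dropna()
    both = turns.dropna(subset=["initiation_latency_s",
                                "completion_latency_s"])
    durations = (both["completion_latency_s"]
                 - both["initiation_latency_s"])
    return SessionSummary(
        turn_ratio=turn_ratio,
        stop_ratio=stop_ratio,
        n_turn_trials=len(turn_trials),
        n_stop_trials=len(stop_trials),
        mean_initiation_s=float(init.mean()) if len(init) else None,
        mean_completion_s=float(comp.mean()) if len(comp) else None,
        mean_turn_duration_s=float(durations.mean()) if len(durations)
        else None,
    )


def criterion_reached(history: list[SessionSummary],
                      ratio: float = CRITERION_RATIO
                      ) -> tuple[bool, int | None]:
    """First session index (0-based) at which the learning criterion holds.

    Requires both the turn and the stop ratio to be >= ``ratio`` on two
    consecutive sessions; returns (False, None) if never reached.
    """
    if not history:
        raise ValueError("history is empty")

    def ok(s: SessionSummary) -> bool:
        return (s.turn_ratio is not None and s.stop_ratio is not None
                and s.turn_ratio >= ratio and s.stop_ratio >= ratio)

    for i in range(1, len(history)):
        if ok(history[i - 1]) and ok(history[i]):
            return True, i
    return False, None
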