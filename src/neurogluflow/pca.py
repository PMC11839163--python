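"""Pavlovian conditioned approach (PCA) scoring and phenotype classification.

The PCA index summarizes whether an animal directs behavior at the lever CS
(sign-tracking) or the food magazine port (goal-tracking) during the 8-s CS
period, as the mean of three components, each in [-1, +1]:

* probability difference  ``P(lever) - P(port)``,
* response bias           ``(lever contacts - port entries) /
  (lever contacts + port entries)``,
* latency score           ``(port latency - lever latency) / 8``.

Trials without a response of a given kind contribute the 8-s cap to that
kind's latency mean; this convention is what pins the index to exactly +1 for
an animal that lever-presses at CS onset on every trial and never enters the
port (and -1 for the mirror image).  Rats are classified on the index
averaged over sessions 4 and 5: GT for [-1, -0.5], ST for [+0.5, +1],
intermediate (IN) otherwise; the boundary values belong to GT/ST.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PCASessionMeasures",
    "PCAIndex",
    "session_measures",
    "compute_pca_index",
    "average_index",
    "classify",
    "score_rats",
]

CS_DURATION_S = 8.0
GT_UPPER = -0.5
ST_LOWER = 0.5
CLASSIFICATION_SESSIONS = (4, 5)


@dataclass(frozen=True)
class PCASessionMeasures:
    lever_contacts: int
    lever_latency_mean: float
    cs_port_entries: int
    port_latency_mean: float
    iti_port_entries: int
    lever_trials: int
    port_trials: int
    n_trials: int


@dataclass(frozen=True)
class PCAIndex:
    prob_diff: float
    resp_bias: float
    latency_score: float
    index: float


def session_measures(trials: pd.DataFrame) -> PCASessionMeasures:
    """Aggregate one session's trial records.

    Expects columns lever_contacts, lever_latency_s, cs_port_entries,
    port_latency_s, iti_port_entries; latencies are NaN on trials without the
    corresponding response and enter the means at the 8-s cap.
    """
    if len(trials) == 0:
        raise ValueError("session has no trials")
    for col in ("lever_latency_s", "port_latency_s"):
        lat = trials[col].to_numpy(dtype=float)
        finite = lat[np.isfinite(lat)]
        if ((finite < 0) | (finite > CS_DURATION_S)).any():
            raise ValueError(f"{col} outside [0, {CS_DURATION_S}] s")

    lever_lat = trials["lever_latency_s"].fillna(CS_DURATION_S)
    port_lat = trials["port_latency_s"].fillna(CS_DURATION_S)
    return PCASessionMeasures(
        lever_contacts=int(trials["lever_contacts"].sum()),
        lever_latency_mean=float(lever_lat.mean()),
        cs_port_entries=int(trials["cs_port_entries"].sum()),
        port_latency_mean=float(port_lat.mean()),
        iti_port_entries=int(trials["iti_port_entries"].sum()),
        lever_trials=int((trials["lever_contacts"] >= 1).sum()),
        port_trials=int((trials["cs_port_entries"] >= 1).sum()),
        n_trials=len(trials),
    )


def compute_pca_index(measures: PCASessionMeasures) -> PCAIndex:
    """The three index components and their mean for one session."""
    n = measures.n_trials
    prob_diff = measures.lever_trials / n - measures.port_trials / n
    total = measures.lever_contacts + measures.cs_port_entries
    resp_bias = ((measures.lever_contacts - measures.cs_port_entries) / total
                 if total else 0.0)
    latency_score = (measures.port_latency_mean
                     - measures.lever_latency_mean) / CS_DURATION_S
    index = (prob_diff + resp_bias + latency_score) / 3.0
    return PCAIndex(prob_diff=prob_diff, resp_bias=resp_bias,
                    latency_score=latency_score, index=index)


def average_index(session_indices: dict[int, PCAIndex],
                  sessions: tuple[int, ...] = CLASSIFICATION_SESSIONS
                  ) -> float:
    """Averaged index over the classification sessions (4 and 5)."""
    missing = [s for s in sessions if s not in session_indices]
    if missing:
        raise ValueError(f"missing sessions for classification: {missing}")
    return float(np.mean([session_indices[s].index for s in sessions]))


def classify(avg_index: float) -> str:
    """Phenotype label from the averaged index; +/-0.5 are inclusive."""
    if not -1.0 <= avg_index <= 1.0:
        raise ValueError("PCA index must lie in [-1, 1]")
    if avg_index <= GT_UPPER:
        return "GT"
    if avg_index >= ST_LOWER:
        return "ST"
    return "IN"


def score_rats(trials: pd.DataFrame,
               sessions: tuple[int, ...] = CLASSIFICATION_SESSIONS
               ) -> pd.DataFrame:
    """Per-rat score table: per-session indices, averaged index, label."""
    rows = []
    for rat_id, rat_df in trials.groupby("rat_id"):
        per_session = {
            int(s): compute_pca_index(session_measures(sdf))
            for s, sdf in rat_df.groupby("session")}
        avg = average_index(per_session, sessions)
        row = {"rat_id": rat_id, "avg_index": avg, "label": classify(avg)}
        for s, ix in sorted(per_session.items()):
            row[f"index_s{s}"] = ix.index
        rows.append(row)
    return pd.DataFrame(rows)
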