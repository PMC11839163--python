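"""Raw dual-channel currents -> event-anchored glutamate concentration windows.

Processing chain, matching the recording convention of glutamate-oxidase
microelectrode arrays with sentinel sites:

1. ``sentinel_subtract`` — remove shared background (drift, electrostatic
   artifacts) by subtracting the sentinel-channel current sample-wise.
2. ``dopamine_normalize`` — electrodes with a dopamine response > 0.1 pA have
   their net current divided by that response, correcting for variation in
   the interferent-exclusion layer.
3. ``to_concentration`` — convert net current to uM glutamate via the
   calibration slope; when step 2 applied, the slope is rescaled by the same
   dopamine response, so the concentration is invariant to normalization.
4. ``extract_windows`` — cut per-trial baseline (2.5 s pre-cue), cue (2 s
   from cue onset) and reward (2 s from reward delivery) windows; cue/reward
   windows are baseline-corrected by their own trial's baseline mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TraceMetadata",
    "DualChannelTrace",
    "ConcentrationTrace",
    "Window",
    "TrialWindows",
    "EventWindowSet",
    "DA_NORMALIZATION_THRESHOLD_PA",
    "sentinel_subtract",
    "dopamine_normalize",
    "to_concentration",
    "extract_windows",
    "read_trace",
    "windows_to_frame",
]

#: Electrodes responding to dopamine above this are normalized by it.
DA_NORMALIZATION_THRESHOLD_PA = 0.1

BASELINE_DURATION_S = 2.5
CUE_WINDOW_S = 2.0
REWARD_WINDOW_S = 2.0


@dataclass
class TraceMetadata:
    electrode_id: str
    sampling_rate: float
    da_response: float
    calibration_ref: str | None = None
    qc_flags: dict = field(default_factory=dict)


@dataclass
class DualChannelTrace:
    """Time-stamped active and sentinel currents (pA)."""

    time: np.ndarray
    active: np.ndarray
    sentinel: np.ndarray
    metadata: TraceMetadata

    def validate(self) -> None:
        if len(self.active) != len(self.sentinel) or \
                len(self.active) != len(self.time):
            raise ValueError("channel/time lengths differ")
        dt = np.diff(self.time)
        if len(dt) and (dt <= 0).any():
            raise ValueError("time must be strictly increasing")
        if len(dt) and (np.abs(dt - dt[0]) > 1e-9).any():
            raise ValueError("time must be uniform")


@dataclass
class ConcentrationTrace:
    time: np.ndarray
    glutamate: np.ndarray  # uM
    sampling_rate: float
    normalization_applied: bool


@dataclass
class Window:
    """One event-anchored sample window (uM, baseline-corrected for
    cue/reward windows)."""

    kind: str                 # baseline | cue | reward
    anchor_time: float        # s, absolute
    t_rel: np.ndarray         # s from anchor
    values: np.ndarray        # uM
    baseline_mean: float
    baseline_sd: float
    sd_floored: bool = False


@dataclass
class TrialWindows:
    trial: int
    outcome: str
    baseline: Window
    cue: Window
    reward: Window | None


@dataclass
class EventWindowSet:
    trials: list[TrialWindows]
    skipped: list[tuple[int, str]]  # (trial, reason)


def sentinel_subtract(trace: DualChannelTrace) -> np.ndarray:
    """Net current: active minus sentinel, sample-wise."""
    trace.validate()
    return trace.active - trace.sentinel


def dopamine_normalize(net: np.ndarray,
                       da_response: float) -> tuple[np.ndarray, bool]:
    """Divide net current by the dopamine response when it exceeds 0.1 pA.

    Returns (series, applied).  Electrodes at or below the threshold pass
    through unchanged.
    """
    if da_response < 0:
        raise ValueError("da_response must be non-negative")
    if da_response > DA_NORMALIZATION_THRESHOLD_PA:
        return net / da_response, True
    return np.asarray(net, dtype=float), False


def to_concentration(net: np.ndarray, calibration, *,
                     normalized: bool, sampling_rate: float,
                     time: np.ndarray | None = None,
                     da_response: float | None = None) -> ConcentrationTrace:
    """Convert (possibly normalized) net current to uM glutamate.

    ``calibration`` is a :class:`~neurogluflow.calibration.CalibrationResult`
    or a bare slope in pA/uM.  When ``normalized`` is true the slope is
    divided by the electrode's dopamine response so that the concentration is
    invariant to whether normalization was applied.
    """
    slope = getattr(calibration, "sensitivity", calibration)
    if slope is None or slope <= 0:
        raise ValueError("calibration slope must be positive")
    if normalized:
        if da_response is None:
            da_response = getattr(calibration, "da_response", None)
        if da_response is None or da_response <= 0:
            raise ValueError("normalized conversion needs a dopamine response")
        slope = slope / da_response
    net = np.asarray(net, dtype=float)
    if time is None:
        time = np.arange(len(net)) / sampling_rate
    return ConcentrationTrace(time=np.asarray(time), glutamate=net / slope,
                              sampling_rate=sampling_rate,
                              normalization_applied=bool(normalized))


def _anchor_index(conc: ConcentrationTrace, t_event: float) -> int:
    """Nearest sample at or after the event time (half-open convention)."""
    fs = conc.sampling_rate
    return int(np.ceil((t_event - conc.time[0]) * fs - 1e-9))


def extract_windows(conc: ConcentrationTrace, events: pd.DataFrame,
                    baseline_duration: float = BASELINE_DURATION_S,
                    cue_duration: float = CUE_WINDOW_S,
                    reward_duration: float = REWARD_WINDOW_S
                    ) -> EventWindowSet:
    """Cut per-trial baseline/cue/reward windows from a concentration trace.

    ``events`` is an event-log frame with at least ``trial``, ``cue_onset_s``
    and optionally ``reward_s`` / ``outcome`` columns.  Window sample counts
    are ``floor(duration * sampling_rate)``; the baseline window ends at the
    cue-onset sample (exclusive) and cue/reward windows start at their
    anchors (half-open on the right).  Cue and reward windows are returned
    baseline-corrected by their own trial's baseline mean.  Events whose full
    windows do not fit inside the trace are skipped, not fatal.
    """
    fs = conc.sampling_rate
    n = len(conc.glutamate)
    n_base = int(np.floor(baseline_duration * fs))
    n_cue = int(np.floor(cue_duration * fs))
    n_rew = int(np.floor(reward_duration * fs))
    eps = float(np.finfo(float).eps)

    trials: list[TrialWindows] = []
    skipped: list[tuple[int, str]] = []
    for row in events.itertuples():
        cue_idx = _anchor_index(conc, row.cue_onset_s)
        if cue_idx - n_base < 0 or cue_idx + n_cue > n:
            skipped.append((int(row.trial), "cue window outside trace"))
            continue
        base_vals = conc.glutamate[cue_idx - n_base:cue_idx]
        b_mean = float(base_vals.mean())
        b_sd = float(base_vals.std(ddof=1))
        floored = b_sd <= 0.0
        if floored:
            b_sd = eps

        baseline = Window(
            kind="baseline", anchor_time=float(conc.time[cue_idx]),
            t_rel=(np.arange(-n_base, 0) / fs),
            values=base_vals - b_mean,
            baseline_mean=b_mean, baseline_sd=b_sd, sd_floored=floored)
        cue = Window(
            kind="cue", anchor_time=float(conc.time[cue_idx]),
            t_rel=np.arange(n_cue) / fs,
            values=conc.glutamate[cue_idx:cue_idx + n_cue] - b_mean,
            baseline_mean=b_mean, baseline_sd=b_sd, sd_floored=floored)

        reward = None
        reward_t = getattr(row, "reward_s", float("nan"))
        if reward_t is not None and np.isfinite(reward_t):
            r_idx = _anchor_index(conc, reward_t)
            if r_idx < 0 or r_idx + n_rew > n:
                skipped.append((int(row.trial), "reward window outside trace"))
            else:
                reward = Window(
                    kind="reward", anchor_time=float(conc.time[r_idx]),
                    t_rel=np.arange(n_rew) / fs,
                    values=conc.glutamate[r_idx:r_idx + n_rew] - b_mean,
                    baseline_mean=b_mean, baseline_sd=b_sd, sd_floored=floored)

        trials.append(TrialWindows(
            trial=int(row.trial),
            outcome=str(getattr(row, "outcome", "")),
            baseline=baseline, cue=cue, reward=reward))
    return EventWindowSet(trials=trials, skipped=skipped)


def read_trace(path: Path | str) -> DualChannelTrace:
    """Read the CSV + JSON-sidecar trace dialect of the synthetic generator."""
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    trace = DualChannelTrace(
        time=df["time_s"].to_numpy(),
        active=df["active_pA"].to_numpy(),
        sentinel=df["sentinel_pA"].to_numpy(),
        metadata=TraceMetadata(
            electrode_id=meta["electrode_id"],
            sampling_rate=float(meta["sampling_rate"]),
            da_response=float(meta["da_response"]),
            calibration_ref=meta.get("calibration_ref"),
            qc_flags=meta.get("qc_flags", {})),
    )
    trace.validate()
    return trace


def windows_to_frame(windows: EventWindowSet) -> pd.DataFrame:
    """Tidy long table: trial, window_kind, sample_index, t_rel_s,
    glutamate_uM."""
    rows = []
    for tw in windows.trials:
        for win in (tw.baseline, tw.cue, tw.reward):
            if win is None:
                continue
            for i, (tr, v) in enumerate(zip(win.t_rel, win.values)):
                rows.append({"trial": tw.trial, "window_kind": win.kind,
                             "sample_index": i, "t_rel_s": tr,
                             "glutamate_uM": v})
    return pd.DataFrame(rows)
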