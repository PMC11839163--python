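"""Event-locked glutamate peak detection and feature extraction.

A sample in a cue- or reward-anchored window counts toward a peak under three
criteria, all expressed in units of the trial's pre-cue baseline statistics
(mean and SD over the 2.5 s preceding cue onset):

1. *Threshold*: the value must exceed baseline mean + 3 SD (strict).
2. *Prominence*: the immediately preceding and subsequent samples must each
   lie at least 1 SD below the value.  The pre-window side is baseline by
   construction and satisfies the drop; the post-window side is evaluated on
   the continuing trace when supplied, else the edge satisfies the drop.
3. *Adjacent run*: within a maximal run of two or more consecutive
   supra-threshold samples that contains no prominence peak and whose range
   (max - min) is smaller than 1 SD, the highest sample is counted once as a
   peak (earliest sample on ties).  Without this rule, sustained elevations
   would contribute no peak at all, since none of their samples is bordered
   on both sides by values 1 SD below.

Features per window: maximum peak concentration (uM), number of peaks, and
time of the maximum peak from the window anchor.  Windows with no peak carry
missing markers (never zero-filled).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BaselineStats",
    "Peak",
    "PeakSet",
    "detect_peaks",
    "peak_features",
    "classify_peak_count",
]

THRESHOLD_SDS = 3.0
DROP_SDS = 1.0


@dataclass(frozen=True)
class BaselineStats:
    """Baseline mean and SD (uM) of the 2.5-s pre-cue period."""

    mean: float
    sd: float

    @classmethod
    def from_window(cls, window) -> "BaselineStats":
        """Build from a baseline :class:`~neurogluflow.traces.Window` (whose
        values are already baseline-mean-centered)."""
        return cls(mean=0.0, sd=window.baseline_sd)


@dataclass(frozen=True)
class Peak:
    index: int
    apex_time_rel: float      # s from window anchor
    concentration: float      # uM
    rule_used: str            # "prominence" | "adjacent_run"


@dataclass
class PeakSet:
    peaks: list[Peak]

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    @property
    def max_peak(self) -> float | None:
        if not self.peaks:
            return None
        return max(p.concentration for p in self.peaks)

    @property
    def time_to_max(self) -> float | None:
        if not self.peaks:
            return None
        best = max(self.peaks, key=lambda p: (p.concentration, -p.index))
        return best.apex_time_rel


def detect_peaks(values: np.ndarray, baseline: BaselineStats,
                 dt: float = 0.2, tail: np.ndarray | None = None,
                 threshold_sds: float = THRESHOLD_SDS,
                 drop_sds: float = DROP_SDS) -> PeakSet:
    """Apply the three-criterion peak definition to one window.

    ``values`` are baseline-corrected uM samples starting at the window
    anchor; ``dt`` is the sample interval (0.2 s at 5 Hz); ``tail`` is the
    optional continuation of the trace past the window end, used only to
    evaluate the drop condition of the last sample.  ``threshold_sds`` and
    ``drop_sds`` default to the published 3 SD / 1 SD rules.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("window is empty")
    if not baseline.sd > 0:
        raise ValueError("baseline SD must be positive")
    mean, sd = baseline.mean, baseline.sd
    n = values.size
    supra = values > mean + threshold_sds * sd
    is_prominence = np.zeros(n, dtype=bool)
    for i in np.flatnonzero(supra):
        v = values[i]
        left_ok = True if i == 0 else values[i - 1] <= v - drop_sds * sd
        if i < n - 1:
            right_ok = values[i + 1] <= v - drop_sds * sd
        elif tail is not None and len(tail) > 0:
            right_ok = tail[0] <= v - drop_sds * sd
        else:
            right_ok = True
        is_prominence[i] = left_ok and right_ok

    peaks: list[Peak] = []
    for i in np.flatnonzero(is_prominence):
        peaks.append(Peak(index=int(i), apex_time_rel=float(i * dt),
                          concentration=float(values[i]),
                          rule_used="prominence"))

    # maximal runs of consecutive supra-threshold samples
    idx = np.flatnonzero(supra)
    if idx.size:
        breaks = np.flatnonzero(np.diff(idx) > 1)
        run_starts = np.concatenate(([0], breaks + 1))
        run_ends = np.concatenate((breaks, [idx.size - 1]))
        for s, e in zip(run_starts, run_ends):
            run = idx[s:e + 1]
            if run.size < 2:
                continue
            if is_prominence[run].any():
                continue
            seg = values[run]
            if seg.max() - seg.min() < drop_sds * sd:
                j = int(run[int(np.argmax(seg))])  # argmax -> earliest tie
                peaks.append(Peak(index=j, apex_time_rel=float(j * dt),
                                  concentration=float(values[j]),
                                  rule_used="adjacent_run"))

    peaks.sort(key=lambda p: p.index)
    return PeakSet(peaks=peaks)


def peak_features(peakset: PeakSet) -> dict:
    """Per-window feature record with missing markers for peak-free windows."""
    return {
        "max_peak_uM": peakset.max_peak,
        "n_peaks": peakset.n_peaks,
        "time_to_max_s": peakset.time_to_max,
        "rules_used": sorted({p.rule_used for p in peakset.peaks}),
    }


def classify_peak_count(features: pd.DataFrame,
                        phenotype_col: str = "phenotype",
                        n_peaks_col: str = "n_peaks") -> pd.DataFrame:
    """Frequency table of 1 / 2 / >=3 peaks per phenotype.

    Windows with zero peaks are excluded from the table and reported in a
    separate ``no_peak`` column.
    """
    def category(n: int) -> str:
        return "1" if n == 1 else ("2" if n == 2 else ">=3")

    out = {}
    for phen, grp in features.groupby(phenotype_col):
        counted = grp[grp[n_peaks_col] >= 1]
        cats = counted[n_peaks_col].map(category)
        out[phen] = {
            "1": int((cats == "1").sum()),
            "2": int((cats == "2").sum()),
            ">=3": int((cats == ">=3").sum()),
            "no_peak": int((grp[n_peaks_col] == 0).sum()),
        }
    table = pd.DataFrame(out).T
    table.index.name = phenotype_col
    return table
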