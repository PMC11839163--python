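"""Contingency statistics for phenotype-stratified turn/miss tables.

The central analysis asks whether goal-trackers (GT) are more likely than
sign-trackers (ST) to turn when turn-cue-locked glutamate peaks have
particular properties.  For each condition (a maximum-peak threshold in uM,
crossed with a peak-count class) a 2x2 table of turns and misses by phenotype
is formed; the tools here compute

* Fisher's exact two-sided p (probability-mass convention),
* the relative turn probability (risk ratio, GT over ST) with its 95%
  Koopman asymptotic-score confidence interval, and
* a Pearson chi-square for r x c frequency tables (peak-count frequencies).

Conditions in the threshold sweep with any cell count below 10 are flagged
``included = False`` and their estimates are not interpreted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

__all__ = [
    "ContingencyTable2x2",
    "RelativeProbabilityResult",
    "fisher_exact",
    "koopman_rr_ci",
    "threshold_sweep",
    "pearson_chi_square",
    "MIN_CELL_COUNT",
]

#: Sweep conditions with any contingency cell below this are excluded.
MIN_CELL_COUNT = 10

CHI2_95 = float(sps.chi2.ppf(0.95, df=1))


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Turn/miss counts by phenotype (GT row first)."""

    gt_turns: int
    gt_misses: int
    st_turns: int
    st_misses: int

    def validate(self) -> None:
        cells = (self.gt_turns, self.gt_misses, self.st_turns, self.st_misses)
        if any(c < 0 for c in cells):
            raise ValueError("cell counts must be non-negative")
        if sum(cells) == 0:
            raise ValueError("table is empty")

    @property
    def gt_total(self) -> int:
        return self.gt_turns + self.gt_misses

    @property
    def st_total(self) -> int:
        return self.st_turns + self.st_misses

    def as_array(self) -> np.ndarray:
        return np.array([[self.gt_turns, self.gt_misses],
                         [self.st_turns, self.st_misses]])

    def swapped(self) -> "ContingencyTable2x2":
        """Phenotype labels exchanged (rows swapped)."""
        return ContingencyTable2x2(self.st_turns, self.st_misses,
                                   self.gt_turns, self.gt_misses)


@dataclass(frozen=True)
class RelativeProbabilityResult:
    rr: float                 # GT turn proportion / ST turn proportion
    ci_low: float
    ci_high: float
    p_fisher: float
    included: bool = True
    one_sided: bool = False   # marks an undefined / degenerate ratio


def fisher_exact(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p (sum of tables at most as probable)."""
    table.validate()
    return float(sps.fisher_exact(table.as_array(),
                                  alternative="two-sided")[1])


def _koopman_chi2(x1: int, n1: int, x2: int, n2: int, rho: float) -> float:
    """Koopman score chi-square for H0: p1/p2 = rho.

    The constrained MLE of p2 solves the quadratic obtained from the profile
    likelihood; the statistic is the sum of the two binomial score terms at
    (rho * p2_tilde, p2_tilde).
    """
    if rho <= 0:
        return math.inf
    s = x1 + x2
    a = rho * (n1 + n2)
    b = -((1 + rho) * s + rho * (n1 - x1) + (n2 - x2))
    c = s
    disc = b * b - 4 * a * c
    disc = max(disc, 0.0)
    p2 = (-b - math.sqrt(disc)) / (2 * a)
    p2 = min(max(p2, 1e-12), 1 - 1e-12)
    p1 = min(max(rho * p2, 1e-12), 1 - 1e-12)
    term1 = (x1 - n1 * p1) ** 2 / (n1 * p1 * (1 - p1))
    term2 = (x2 - n2 * p2) ** 2 / (n2 * p2 * (1 - p2))
    return term1 + term2


def koopman_rr_ci(table: ContingencyTable2x2,
                  level: float = 0.95) -> RelativeProbabilityResult:
    """Risk ratio with its Koopman asymptotic-score confidence interval.

    The interval is the set of ratio values whose score chi-square does not
    exceed the level's chi-square quantile; the bounds are found by bisection
    on each side of the point estimate (the statistic is continuous and
    unimodal in log rho, zero at the unconstrained MLE).
    """
    table.validate()
    x1, n1 = table.gt_turns, table.gt_total
    x2, n2 = table.st_turns, table.st_total
    if n1 == 0 or n2 == 0:
        raise ValueError("both phenotype totals must be positive")
    p = fisher_exact(table)
    crit = float(sps.chi2.ppf(level, df=1))

    if x2 == 0:
        # ST turn proportion zero: the ratio is undefined; report a
        # one-sided lower bound when GT turns exist.
        if x1 == 0:
            return RelativeProbabilityResult(
                rr=math.nan, ci_low=0.0, ci_high=math.inf, p_fisher=p,
                one_sided=True)
        low = _invert_side(x1, n1, x2, n2, crit, side="lower",
                           start=(x1 / n1) * n2)  # finite probe point
        return RelativeProbabilityResult(
            rr=math.inf, ci_low=low, ci_high=math.inf, p_fisher=p,
            one_sided=True)

    rr = (x1 / n1) / (x2 / n2)
    if x1 == 0:
        high = _invert_side(x1, n1, x2, n2, crit, side="upper",
                            start=1.0 / n1)
        return RelativeProbabilityResult(
            rr=0.0, ci_low=0.0, ci_high=high, p_fisher=p, one_sided=True)

    low = _invert_side(x1, n1, x2, n2, crit, side="lower", start=rr)
    high = _invert_side(x1, n1, x2, n2, crit, side="upper", start=rr)
    return RelativeProbabilityResult(rr=rr, ci_low=low, ci_high=high,
                                     p_fisher=p)


def _invert_side(x1, n1, x2, n2, crit, side: str, start: float) -> float:
    """Root of ``chi2(rho) - crit`` on one side of ``start`` (where the
    statistic is below the critical value)."""
    def f(log_rho: float) -> float:
        return _koopman_chi2(x1, n1, x2, n2, math.exp(log_rho)) - crit

    log_start = math.log(max(start, 1e-12))
    step = 0.5
    # make sure the probe point lies inside the confidence set
    guard = 0
    while f(log_start) > 0 and guard < 200:
        log_start += step if side == "lower" else -step
        guard += 1
    if guard >= 200:
        return 0.0 if side == "lower" else math.inf
    if side == "lower":
        lo = log_start
        for _ in range(200):
            lo -= step
            if f(lo) > 0:
                return float(math.exp(
                    optimize.brentq(f, lo, lo + step, xtol=1e-10)))
        return 0.0
    hi = log_start
    for _ in range(200):
        hi += step
        if f(hi) > 0:
            return float(math.exp(
                optimize.brentq(f, hi - step, hi, xtol=1e-10)))
    return math.inf


PEAK_CLASSES = ("any", "single", "multi")


def _class_predicate(n_peaks: pd.Series, peak_class: str) -> pd.Series:
    if peak_class == "any":
        return n_peaks >= 1
    if peak_class == "single":
        return n_peaks == 1
    if peak_class == "multi":
        return n_peaks.isin((2, 3))
    raise ValueError(f"unknown peak class {peak_class!r}")


def threshold_sweep(features: pd.DataFrame, thresholds: Sequence[float],
                    peak_classes: Sequence[str] = PEAK_CLASSES,
                    min_cell: int = MIN_CELL_COUNT) -> pd.DataFrame:
    """Contingency sweep over maximum-peak thresholds and peak-count classes.

    ``features`` needs columns phenotype (GT/ST), outcome (turn/miss),
    max_peak_uM and n_peaks.  A trace enters the (threshold, class) condition
    when ``max_peak_uM >= threshold`` and the class predicate holds
    (single: exactly one peak; multi: two or three).  Conditions with any
    cell below ``min_cell`` are marked not included; rr, CI and Fisher p are
    still reported for completeness.
    """
    if len(features) == 0:
        raise ValueError("empty feature set")
    required = {"phenotype", "outcome", "max_peak_uM", "n_peaks"}
    missing = required - set(features.columns)
    if missing:
        raise ValueError(f"features missing columns: {sorted(missing)}")

    rows = []
    for peak_class in peak_classes:
        cls_mask = _class_predicate(features["n_peaks"], peak_class)
        for thr in thresholds:
            sel = features[cls_mask
                           & (features["max_peak_uM"] >= thr)]
            cells = {}
            for phen in ("GT", "ST"):
                for out, cell in (("turn", "turns"), ("miss", "misses")):
                    cells[f"{phen.lower()}_{cell}"] = int(
                        ((sel["phenotype"] == phen)
                         & (sel["outcome"] == out)).sum())
            table = ContingencyTable2x2(**cells)
            included = all(v >= min_cell for v in cells.values())
            row = {"threshold_uM": thr, "peak_class": peak_class,
                   **cells, "n_traces": len(sel), "included": included}
            try:
                res = koopman_rr_ci(table)
                row.update(rr=res.rr, ci_low=res.ci_low, ci_high=res.ci_high,
                           p_fisher=res.p_fisher)
            except ValueError:
                row.update(rr=math.nan, ci_low=math.nan, ci_high=math.nan,
                           p_fisher=math.nan)
            rows.append(row)
    return pd.DataFrame(rows)


def pearson_chi_square(freq_table: np.ndarray
                       ) -> tuple[float, int, float]:
    """Pearson chi-square for an r x c frequency table (no continuity
    correction); returns (statistic, df, p)."""
    obs = np.asarray(freq_table, dtype=float)
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero margin")
    stat, p, df, _ = sps.chi2_contingency(obs, correction=False)
    return float(stat), int(df), float(p)
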