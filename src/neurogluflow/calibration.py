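"""In-vitro electrode calibration: sensitivity, selectivity, LOD, linearity.

A calibration series is a beaker recording in which known analyte additions
(ascorbate, cumulative glutamate steps, dopamine) produce plateau current
shifts.  The fit measures, per electrode:

* **sensitivity** — least-squares slope (intercept-free) of glutamate plateau
  shift vs cumulative glutamate concentration, in pA/uM;
* **linearity** — Pearson correlation R of plateau shift vs concentration
  (R^2 also reported);
* **LOD** — limit of detection, ``3 * baseline current SD / sensitivity``;
* **selectivity** — glutamate sensitivity over ascorbate sensitivity;
* **da_response** — plateau shift following the dopamine addition, the
  largest across glutamate-sensing sites.

Electrode acceptance requires sensitivity > 5 pA/uM, LOD < 1.0 uM,
selectivity > 50:1, dopamine response < 3 pA, and linearity R > 0.95.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import CalibrationSeriesData

__all__ = [
    "CalibrationResult",
    "CRITERIA",
    "fit_calibration",
    "evaluate_criteria",
    "read_calibration_series",
    "write_calibration_result",
    "read_calibration_result",
]

#: Published electrode acceptance thresholds.
CRITERIA = {
    "sensitivity_min_pA_per_uM": 5.0,
    "lod_max_uM": 1.0,
    "selectivity_min": 50.0,
    "da_response_max_pA": 3.0,
    "linearity_r_min": 0.95,
}


@dataclass
class CalibrationResult:
    sensitivity: float        # pA/uM
    linearity_r: float        # Pearson R of plateau shift vs concentration
    linearity_r2: float
    lod: float                # uM
    selectivity: float        # ratio; inf marks a zero ascorbate response
    da_response: float        # pA
    baseline_sd: float        # pA
    per_site_sensitivity: dict[str, float]
    passed: dict[str, bool]
    selectivity_flagged: bool = False

    @property
    def passed_all(self) -> bool:
        return all(self.passed.values())


def _plateau(time: np.ndarray, current: np.ndarray, end: float,
             window: float) -> float:
    """Mean current over the ``window`` seconds preceding ``end``."""
    mask = (time >= end - window) & (time < end)
    if not mask.any():
        raise ValueError("empty plateau window")
    return float(current[mask].mean())


def fit_calibration(series: CalibrationSeriesData,
                    plateau_window: float = 10.0) -> CalibrationResult:
    """Fit one calibration series to a :class:`CalibrationResult`.

    Plateaus are estimated as the mean over the last ``plateau_window``
    seconds before the next addition (or the series end).  Glutamate plateau
    shifts are referenced to the plateau immediately preceding the first
    glutamate addition, so the ascorbate response does not leak into the
    intercept-free slope.
    """
    additions = list(series.additions)
    if not additions:
        raise ValueError("series contains no additions")
    times = [t for _, _, t in additions]
    if times != sorted(times) or len(set(times)) != len(times):
        raise ValueError("additions must be strictly increasing in time")
    glut = [(c, t) for a, c, t in additions if a == "glutamate"]
    if not glut:
        raise ValueError("series contains no glutamate additions")
    concs = [c for c, _ in glut]
    if concs != sorted(concs) or len(set(concs)) != len(concs):
        raise ValueError("glutamate concentrations must be strictly increasing")

    t = series.time
    # plateau boundary for each addition = next addition time, or series end
    bounds = times[1:] + [float(t[-1]) + 1.0 / max(len(t), 1)]
    first_add_t = times[0]

    active_sites = [s for s, r in series.site_roles.items() if r == "active"]
    if not active_sites:
        raise ValueError("series has no active (glutamate-sensing) sites")

    per_site_slope: dict[str, float] = {}
    per_site_r: dict[str, float] = {}
    per_site_aa: dict[str, float] = {}
    per_site_da: dict[str, float] = {}
    baseline_sds = []
    for site in active_sites:
        cur = series.currents[site]
        base_mask = t < first_add_t
        baseline_mean = float(cur[base_mask].mean())
        baseline_sds.append(float(cur[base_mask].std(ddof=1)))

        plateaus = {}
        for (analyte, conc, at), end in zip(additions, bounds):
            plateaus[(analyte, conc)] = _plateau(t, cur, end, plateau_window)

        # reference for glutamate shifts: plateau just before the first
        # glutamate addition (post-AA if AA precedes it, else the baseline)
        first_glut_idx = next(i for i, (a, _, _) in enumerate(additions)
                              if a == "glutamate")
        if first_glut_idx == 0:
            glut_ref = baseline_mean
        else:
            prev = additions[first_glut_idx - 1]
            glut_ref = plateaus[(prev[0], prev[1])]

        shifts = np.array([plateaus[("glutamate", c)] - glut_ref
                           for c in concs])
        x = np.asarray(concs, dtype=float)
        slope = float(np.dot(x, shifts) / np.dot(x, x))  # intercept-free LSQ
        per_site_slope[site] = slope
        if len(x) >= 2 and np.std(shifts) > 0:
            per_site_r[site] = float(np.corrcoef(x, shifts)[0, 1])
        else:
            per_site_r[site] = float("nan")

        aa_adds = [(c, i) for i, (a, c, _) in enumerate(additions) if a == "AA"]
        if aa_adds:
            c_aa, i_aa = aa_adds[0]
            ref = baseline_mean if i_aa == 0 else plateaus[
                (additions[i_aa - 1][0], additions[i_aa - 1][1])]
            per_site_aa[site] = (plateaus[("AA", c_aa)] - ref) / c_aa
        da_adds = [(c, i) for i, (a, c, _) in enumerate(additions)
                   if a == "dopamine"]
        if da_adds:
            c_da, i_da = da_adds[0]
            ref = baseline_mean if i_da == 0 else plateaus[
                (additions[i_da - 1][0], additions[i_da - 1][1])]
            per_site_da[site] = plateaus[("dopamine", c_da)] - ref

    sensitivity = float(np.mean(list(per_site_slope.values())))
    linearity_r = float(np.mean(list(per_site_r.values())))
    baseline_sd = float(np.mean(baseline_sds))
    lod = 3.0 * baseline_sd / sensitivity if sensitivity > 0 else math.inf

    selectivity_flagged = False
    if per_site_aa:
        aa_sens = float(np.mean(list(per_site_aa.values())))
        if aa_sens <= 0:
            selectivity = math.inf
            selectivity_flagged = True
        else:
            selectivity = sensitivity / aa_sens
    else:
        selectivity = math.inf
        selectivity_flagged = True

    da_response = float(max(per_site_da.values())) if per_site_da else 0.0

    result = CalibrationResult(
        sensitivity=sensitivity,
        linearity_r=linearity_r,
        linearity_r2=linearity_r ** 2,
        lod=lod,
        selectivity=selectivity,
        da_response=da_response,
        baseline_sd=baseline_sd,
        per_site_sensitivity=per_site_slope,
        passed={},
        selectivity_flagged=selectivity_flagged,
    )
    result.passed = evaluate_criteria(result)
    return result


def evaluate_criteria(result: CalibrationResult) -> dict[str, bool]:
    """Apply the electrode acceptance criteria; one flag per criterion.

    The dopamine criterion is a strict inequality (< 3 pA); likewise the
    sensitivity, selectivity and linearity minima are strict.
    """
    for name in ("sensitivity", "lod", "selectivity", "da_response",
                 "linearity_r"):
        value = getattr(result, name)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise ValueError(f"calibration result field {name!r} is missing")
    flags = {
        "sensitivity": result.sensitivity
        > CRITERIA["sensitivity_min_pA_per_uM"],
        "lod": result.lod < CRITERIA["lod_max_uM"],
        "selectivity": result.selectivity > CRITERIA["selectivity_min"],
        "da_response": result.da_response < CRITERIA["da_response_max_pA"],
        "linearity": result.linearity_r > CRITERIA["linearity_r_min"],
    }
    flags["overall"] = all(flags.values())
    return flags


def read_calibration_series(path: Path | str) -> CalibrationSeriesData:
    """Read the currents CSV + ``*_additions.csv`` pair written by the
    synthetic generator."""
    path = Path(path)
    df = pd.read_csv(path)
    add = pd.read_csv(path.with_name(path.stem + "_additions.csv"))
    sites = [c for c in df.columns if c != "time_s"]
    roles = {s: ("active" if s.startswith("active") else "sentinel")
             for s in sites}
    return CalibrationSeriesData(
        time=df["time_s"].to_numpy(),
        currents={s: df[s].to_numpy() for s in sites},
        site_roles=roles,
        additions=tuple(
            (r.analyte, float(r.final_concentration_uM), float(r.time_s))
            for r in add.itertuples()),
    )


def write_calibration_result(result: CalibrationResult,
                             path: Path | str) -> None:
    payload = asdict(result)
    payload["passed_all"] = result.passed_all
    Path(path).write_text(json.dumps(payload, indent=1, default=str))


def read_calibration_result(path: Path | str) -> CalibrationResult:
    payload = json.loads(Path(path).read_text())
    payload.pop("passed_all", None)
    for key in ("sensitivity", "linearity_r", "linearity_r2", "lod",
                "selectivity", "da_response", "baseline_sd"):
        payload[key] = float(payload[key])
    return CalibrationResult(**payload)
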