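#!/usr/bin/env python
"""Fit the cohort's calibration series and check electrode acceptance.

Reads results/data/calibration_series.csv, fits sensitivity, linearity,
limit of detection, selectivity, and dopamine response, evaluates the
acceptance criteria (>5 pA/uM, R > 0.95, LOD < 1 uM, >50:1, <3 pA), and
writes results/calibration.json.
"""

import json
from pathlib import Path

from neurogluflow.calibration import (
    CRITERIA,
    fit_calibration,
    read_calibration_series,
    write_calibration_result,
)

DATA = Path("results/data")


def main() -> None:
    series = read_calibration_series(DATA / "calibration_series.csv")
    result = fit_calibration(series)
    write_calibration_result(result, Path("results/calibration.json"))

    print("electrode calibration")
    print(f"  sensitivity : {result.sensitivity:7.2f} pA/uM   "
          f"(criterion > {CRITERIA['sensitivity_min_pA_per_uM']})")
    print(f"  linearity R : {result.linearity_r:7.4f}        "
          f"(criterion > {CRITERIA['linearity_r_min']})")
    print(f"  LOD         : {result.lod:7.3f} uM      "
          f"(criterion < {CRITERIA['lod_max_uM']})")
    print(f"  selectivity : {result.selectivity:7.1f} : 1    "
          f"(criterion > {CRITERIA['selectivity_min']})")
    print(f"  DA response : {result.da_response:7.3f} pA     "
          f"(criterion < {CRITERIA['da_response_max_pA']})")
    print(f"  -> passed all criteria: {result.passed['overall']}")
    print(json.dumps(result.passed, indent=1))


if __name__ == "__main__":
    main()
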