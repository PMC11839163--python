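#!/usr/bin/env python
"""Simulate a recording cohort and write its raw-data files.

Generates, for 4 goal-trackers and 4 sign-trackers: an in-vitro calibration
series for the shared electrode lot, five PCA screening sessions per rat,
and two cued-turning sessions per rat with their dual-channel 5 Hz current
traces.  Files land under results/data/ in the package's CSV dialects
(trace CSV + JSON sidecar, event-log CSV, calibration CSV + addition log).
"""

from pathlib import Path

import pandas as pd

from neurogluflow.pipeline import CohortConfig, RunConfig
from neurogluflow.synthetic import (
    gen_calibration_series,
    gen_cttt_session,
    gen_glutamate_trace,
    gen_pca_sessions,
    write_calibration_series,
    write_event_log,
    write_trace,
)

SEED = 2024
OUT = Path("results/data")


def child(k, *more):
    import numpy as np
    return int(np.random.SeedSequence(SEED, spawn_key=(k, *more))
               .generate_state(1)[0] % (2 ** 31))


def main() -> None:
    cfg = RunConfig(seed=SEED)
    cohort = CohortConfig()
    OUT.mkdir(parents=True, exist_ok=True)

    series = gen_calibration_series(cfg.generator.electrode_params,
                                    noise_sd=cohort.calibration_noise_sd,
                                    seed=child(1))
    write_calibration_series(series, OUT / "calibration_series.csv")

    pca_frames = []
    n_sessions = 0
    rats = ([("GT", i) for i in range(cohort.n_gt)]
            + [("ST", i) for i in range(cohort.n_st)])
    for r, (phen, i) in enumerate(rats):
        rat_id = f"{phen}{i:02d}"
        pca_frames.append(gen_pca_sessions(phen, cohort.pca_sessions,
                                           seed=child(2, r), rat_id=rat_id))
        for s in range(cohort.sessions_per_rat):
            sched = gen_cttt_session(cfg.generator, phen, seed=child(3, r, s))
            trace = gen_glutamate_trace(sched, cfg.generator, phen,
                                        seed=child(4, r, s),
                                        electrode_id=rat_id)
            write_event_log(sched, OUT / f"{rat_id}_s{s}_events.csv")
            write_trace(trace, OUT / f"{rat_id}_s{s}_trace.csv")
            n_sessions += 1
    pd.concat(pca_frames, ignore_index=True).to_csv(
        OUT / "pca_trials.csv", index=False)

    print(f"wrote 1 calibration series, {len(rats)} rats x "
          f"{cohort.pca_sessions} PCA sessions, and {n_sessions} "
          f"cued-turning sessions with traces to {OUT}/")


if __name__ == "__main__":
    main()
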