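#!/usr/bin/env python
"""Recover the sign-tracker second-peak latency structure.

Generates 500 two-peak ST cue windows, runs peak detection on an extended
3.5-s cue-anchored window (the 1.58 +/- 0.39 s latency distribution spills
past the 2-s cue period), and compares the recovered mean second-peak apex
latency with the generator's 1.58-s target.  Writes
results/second_peak_latency.csv.
"""

import numpy as np
import pandas as pd

from neurogluflow.peaks import BaselineStats, detect_peaks
from neurogluflow.synthetic import GeneratorConfig, gen_cue_window

SEED = 2024
N = 500


def main() -> None:
    config = GeneratorConfig(seed=SEED)
    target = config.params_for("ST").extra_peak_latency_means[0]
    rows = []
    for i in range(N):
        base, win, apexes, _ = gen_cue_window(config, "ST", seed=SEED + i,
                                              n_peaks=2)
        bs = BaselineStats(0.0, float(np.std(base, ddof=1)))
        ps = detect_peaks(win, bs, dt=0.2)
        rows.append({
            "window": i,
            "drawn_second_apex_s": apexes[1],
            "n_peaks_detected": ps.n_peaks,
            "detected_second_apex_s": (ps.peaks[1].apex_time_rel
                                       if ps.n_peaks >= 2 else np.nan),
        })
    df = pd.DataFrame(rows)
    df.to_csv("results/second_peak_latency.csv", index=False,
              float_format="%.4f")

    det = df.detected_second_apex_s.dropna()
    print(f"two-peak windows generated: {N}; with >=2 detected peaks: "
          f"{len(det)} ({len(det)/N:.0%})")
    print(f"drawn second-apex mean    : {df.drawn_second_apex_s.mean():.3f} s")
    print(f"detected second-apex mean : {det.mean():.3f} s "
          f"(target {target} s, tolerance +/-0.1 s)")
    print(f"detected second-apex SD   : {det.std(ddof=1):.3f} s")


if __name__ == "__main__":
    main()
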