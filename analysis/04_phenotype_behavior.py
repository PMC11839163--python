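#!/usr/bin/env python
"""Score PCA screening and cued-turning behavior.

PCA: per-session indices, the averaged session 4-5 index, and GT/IN/ST
labels (results/pca_scores.csv).  CTTT: trial outcomes, session ratios, turn
timing, and the 70%-for-two-sessions learning criterion
(results/cttt_summaries.csv).
"""

from dataclasses import asdict
from pathlib import Path

import pandas as pd

from neurogluflow.cttt import criterion_reached, score_session, summarize_session
from neurogluflow.pca import score_rats

DATA = Path("results/data")


def main() -> None:
    pca_trials = pd.read_csv(DATA / "pca_trials.csv")
    scores = score_rats(pca_trials)
    scores.to_csv("results/pca_scores.csv", index=False, float_format="%.4f")
    print("PCA classification (averaged sessions 4-5):")
    print(scores[["rat_id", "avg_index", "label"]].to_string(index=False))
    agreement = (scores.label == scores.rat_id.str[:2]).mean()
    print(f"labels matching the generating phenotype: {agreement:.0%}\n")

    rows = []
    outcome_frames = []
    for events_path in sorted(DATA.glob("*_events.csv")):
        stem = events_path.name.replace("_events.csv", "")
        rat_id, session = stem.rsplit("_s", 1)
        outcomes = score_session(pd.read_csv(events_path))
        outcomes.insert(0, "session", int(session))
        outcomes.insert(0, "rat_id", rat_id)
        outcome_frames.append(outcomes)
        rows.append({"rat_id": rat_id, "session": int(session),
                     **asdict(summarize_session(outcomes))})
    pd.concat(outcome_frames, ignore_index=True).to_csv(
        "results/cttt_outcomes.csv", index=False, float_format="%.3f")
    summaries = pd.DataFrame(rows)
    summaries.to_csv("results/cttt_summaries.csv", index=False,
                     float_format="%.4f")

    print("CTTT session summaries:")
    print(summaries[["rat_id", "session", "turn_ratio", "stop_ratio",
                     "mean_initiation_s", "mean_turn_duration_s"]]
          .to_string(index=False))
    for rat_id, grp in summaries.groupby("rat_id"):
        hist = [summarize_session(pd.read_csv(
            DATA / f"{rat_id}_s{int(s)}_events.csv").pipe(score_session))
            for s in grp.session]
        reached, idx = criterion_reached(hist)
        print(f"  {rat_id}: learning criterion reached = {reached}"
              + (f" at session {idx}" if reached else ""))


if __name__ == "__main__":
    main()
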