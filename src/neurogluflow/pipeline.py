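"""End-to-end orchestration: generate -> calibrate -> process -> detect ->
score -> sweep, with a reproducible run manifest.

A run fans the root seed out to per-stage, per-rat child seeds through
``numpy.random.SeedSequence`` spawn keys, so identical (config, seed) pairs
produce byte-identical outputs and individual stages can be re-derived from
the intermediate CSV files alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calibration as cal
from . import cttt, pca, peaks, stats, synthetic, traces

__all__ = [
    "ProcessingConfig",
    "SweepConfig",
    "CohortConfig",
    "RunConfig",
    "RunManifest",
    "run_pipeline",
]

log = logging.getLogger("neurogluflow")


@dataclass(frozen=True)
class ProcessingConfig:
    baseline_duration: float = 2.5   # s before cue onset
    cue_duration: float = 2.0        # s from cue onset
    reward_duration: float = 2.0     # s from reward delivery
    threshold_sds: float = 3.0
    drop_sds: float = 1.0


@dataclass(frozen=True)
class SweepConfig:
    thresholds: tuple[float, ...] = (2.0, 2.8, 4.0, 6.0, 8.0, 10.0)
    peak_classes: tuple[str, ...] = ("any", "single", "multi")
    min_cell: int = 10


@dataclass(frozen=True)
class CohortConfig:
    n_gt: int = 4
    n_st: int = 4
    sessions_per_rat: int = 2
    pca_sessions: int = 5
    calibration_noise_sd: float = 1.2   # pA


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    generator: synthetic.GeneratorConfig = field(
        default_factory=synthetic.GeneratorConfig)
    processing: ProcessingConfig = field(default_factory=ProcessingConfig)
    sweep: SweepConfig = field(default_factory=SweepConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        gen = d.get("generator", {})
        phen = {
            label: synthetic.PhenotypeParams(**{
                **params, **{k: tuple(v) for k, v in params.items()
                             if isinstance(v, list)}})
            for label, params in gen.pop("phenotype_params", {}).items()
        } or None
        elec = gen.pop("electrode_params", None)
        gen_cfg = synthetic.GeneratorConfig(
            **gen,
            **({"phenotype_params": phen} if phen else {}),
            **({"electrode_params": synthetic.ElectrodeParams(**elec)}
               if elec else {}))
        sweep = d.get("sweep", {})
        if "thresholds" in sweep:
            sweep["thresholds"] = tuple(sweep["thresholds"])
        if "peak_classes" in sweep:
            sweep["peak_classes"] = tuple(sweep["peak_classes"])
        return cls(
            seed=int(d.get("seed", 0)),
            generator=gen_cfg,
            processing=ProcessingConfig(**d.get("processing", {})),
            sweep=SweepConfig(**sweep),
            cohort=CohortConfig(**d.get("cohort", {})),
        )

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stage_counts: dict
    outputs: list[str]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


def _child_seed(seed: int, *keys: int) -> int:
    ss = np.random.SeedSequence(seed, spawn_key=keys)
    return int(ss.generate_state(1)[0] % (2 ** 31))


def filter_traces(trial_windows, qc_flags: dict) -> bool:
    """A trace is included unless any QC flag is raised.

    Flags (artifact_detected, task_noncompliance, placement_rejected) mirror
    the study's inclusion judgments; they are inputs to the pipeline, not
    derived from the signal.
    """
    return not any(bool(v) for v in qc_flags.values())


def process_session(trace: traces.DualChannelTrace, events: pd.DataFrame,
                    calib, processing: ProcessingConfig) -> pd.DataFrame:
    """One session's trace -> per-trial, per-event-kind peak features."""
    net = traces.sentinel_subtract(trace)
    net, applied = traces.dopamine_normalize(net, trace.metadata.da_response)
    conc = traces.to_concentration(
        net, calib, normalized=applied,
        sampling_rate=trace.metadata.sampling_rate, time=trace.time,
        da_response=trace.metadata.da_response)
    wins = traces.extract_windows(
        conc, events,
        baseline_duration=processing.baseline_duration,
        cue_duration=processing.cue_duration,
        reward_duration=processing.reward_duration)
    dt = 1.0 / trace.metadata.sampling_rate
    rows = []
    for tw in wins.trials:
        for kind, win in (("cue", tw.cue), ("reward", tw.reward)):
            if win is None:
                continue
            ps = peaks.detect_peaks(
                win.values, peaks.BaselineStats.from_window(win), dt=dt,
                threshold_sds=processing.threshold_sds,
                drop_sds=processing.drop_sds)
            feats = peaks.peak_features(ps)
            rows.append({
                "trial": tw.trial, "event_kind": kind,
                "outcome": tw.outcome,
                "max_peak_uM": feats["max_peak_uM"],
                "n_peaks": feats["n_peaks"],
                "time_to_max_s": feats["time_to_max_s"],
                "rules_used": "|".join(feats["rules_used"]),
            })
    return pd.DataFrame(rows)


def _trace_bookkeeping(features: pd.DataFrame) -> dict:
    """Per-phenotype, per-event-category trace counts (ranges and medians of
    traces per rat)."""
    out: dict = {}
    for (phen, kind, outcome), grp in features.groupby(
            ["phenotype", "event_kind", "outcome"]):
        per_rat = grp.groupby("rat_id").size()
        out[f"{phen}/{kind}/{outcome}"] = {
            "total": int(len(grp)),
            "per_rat_min": int(per_rat.min()),
            "per_rat_max": int(per_rat.max()),
            "per_rat_median": float(per_rat.median()),
        }
    return out


def run_pipeline(config: RunConfig, out_dir: Path | str) -> RunManifest:
    """Execute every stage, writing CSV/JSON outputs under ``out_dir``.

    On a stage failure all partial outputs of this run are removed and the
    error is re-raised with a stage tag.
    """
    config.generator.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    counts: dict = {}

    def save_csv(df: pd.DataFrame, name: str) -> None:
        p = out / name
        df.to_csv(p, index=False, float_format="%.6g")
        written.append(p)

    stage = "setup"
    try:
        # --- calibration -------------------------------------------------
        stage = "calibrate"
        series = synthetic.gen_calibration_series(
            config.generator.electrode_params,
            noise_sd=config.cohort.calibration_noise_sd,
            seed=_child_seed(config.seed, 10))
        calib = cal.fit_calibration(series)
        if not calib.passed_all:
            raise ValueError("synthetic electrode failed calibration criteria")
        p = out / "calibration.json"
        cal.write_calibration_result(calib, p)
        written.append(p)
        counts["calibration"] = {"passed": calib.passed_all}
        log.info("calibrate: sensitivity=%.2f pA/uM, passed=%s",
                 calib.sensitivity, calib.passed_all)

        # --- cohort ------------------------------------------------------
        stage = "generate"
        rats = ([("GT", i) for i in range(config.cohort.n_gt)]
                + [("ST", i) for i in range(config.cohort.n_st)])
        feature_rows = []
        outcome_rows = []
        pca_frames = []
        n_generated = n_included = 0
        for r, (phen, i) in enumerate(rats):
            rat_id = f"{phen}{i:02d}"
            pca_frames.append(synthetic.gen_pca_sessions(
                phen, config.cohort.pca_sessions,
                seed=_child_seed(config.seed, 20, r), rat_id=rat_id))
            for s in range(config.cohort.sessions_per_rat):
                sched = synthetic.gen_cttt_session(
                    config.generator, phen,
                    seed=_child_seed(config.seed, 30, r, s))
                trace = synthetic.gen_glutamate_trace(
                    sched, config.generator, phen,
                    seed=_child_seed(config.seed, 40, r, s),
                    electrode_id=rat_id)
                n_generated += 1
                if not filter_traces(None, trace.metadata.qc_flags):
                    continue
                n_included += 1
                feats = process_session(trace, sched.events, calib,
                                        config.processing)
                feats.insert(0, "session", s)
                feats.insert(0, "phenotype", phen)
                feats.insert(0, "rat_id", rat_id)
                feature_rows.append(feats)

                scored = cttt.score_session(sched.events)
                scored.insert(0, "session", s)
                scored.insert(0, "phenotype", phen)
                scored.insert(0, "rat_id", rat_id)
                outcome_rows.append(scored)
        counts["traces"] = {"generated": n_generated,
                            "included": n_included,
                            "excluded": n_generated - n_included}
        log.info("generate: %d sessions (%d included)",
                 n_generated, n_included)

        # --- behavioral scoring -------------------------------------------
        stage = "score"
        pca_trials = pd.concat(pca_frames, ignore_index=True)
        save_csv(pca_trials, "pca_trials.csv")
        pca_scores = pca.score_rats(
            pca_trials, sessions=tuple(
                range(max(1, config.cohort.pca_sessions - 1),
                      config.cohort.pca_sessions + 1)))
        save_csv(pca_scores, "pca_scores.csv")

        outcomes = pd.concat(outcome_rows, ignore_index=True)
        save_csv(outcomes, "cttt_outcomes.csv")
        summary_rows = []
        for (rat_id, session), grp in outcomes.groupby(["rat_id", "session"]):
            s = cttt.summarize_session(grp)
            summary_rows.append({"rat_id": rat_id, "session": session,
                                 **asdict(s)})
        save_csv(pd.DataFrame(summary_rows), "cttt_session_summaries.csv")
        counts["behavior"] = {"pca_rats": len(pca_scores),
                              "cttt_sessions": len(summary_rows)}

        # --- peak features -------------------------------------------------
        stage = "peaks"
        features = pd.concat(feature_rows, ignore_index=True)
        save_csv(features, "peak_features.csv")
        counts["peaks"] = {
            "windows": int(len(features)),
            "with_peaks": int((features["n_peaks"] > 0).sum()),
        }
        counts["trace_bookkeeping"] = _trace_bookkeeping(features)

        # --- contingency sweep ---------------------------------------------
        stage = "sweep"
        cue_feats = features[
            (features["event_kind"] == "cue")
            & features["outcome"].isin(["cued_turn", "miss"])
            & features["max_peak_uM"].notna()].copy()
        cue_feats["outcome"] = cue_feats["outcome"].map(
            {"cued_turn": "turn", "miss": "miss"})
        sweep = stats.threshold_sweep(
            cue_feats, thresholds=config.sweep.thresholds,
            peak_classes=config.sweep.peak_classes,
            min_cell=config.sweep.min_cell)
        save_csv(sweep, "sweep.csv")
        counts["sweep"] = {
            "conditions": int(len(sweep)),
            "included": int(sweep["included"].sum()),
        }
        excluded = sweep[~sweep["included"]]
        if len(excluded):
            log.warning("sweep: %d conditions excluded by the min-cell rule",
                        len(excluded))

        # --- manifest ------------------------------------------------------
        stage = "manifest"
        manifest = RunManifest(
            config_hash=config.config_hash(), seed=config.seed,
            stage_counts=counts,
            outputs=sorted(str(p.relative_to(out)) for p in written))
        (out / "manifest.json").write_text(manifest.to_json())
        return manifest
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
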