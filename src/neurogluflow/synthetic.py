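"""Synthetic data generators for the glutamate-amperometry pipeline.

Every downstream stage of the pipeline (calibration fitting, sentinel
subtraction, event-window extraction, peak detection, behavioral scoring,
contingency statistics) is exercised against data produced here, so the
generators emulate the statistical structure the analyses assume:

* 5 Hz dual-channel amperometric currents: an *active* channel carrying
  glutamate-oxidase-derived current and a *sentinel* channel carrying only
  shared background (drift, electrostatic artifacts).  Glutamate transients
  are injected into the active channel only, anchored to behavioral events.
* Phenotype-dependent peak structure: goal-trackers (GT) predominantly show a
  single, high-amplitude turn-cue-locked transient; sign-trackers (ST) show
  two or three smaller transients, the later apexes centered at 1.58 s and
  1.83 s after cue onset, and larger reward-locked transients.
* Cued-turning (CTTT) session schedules: 18 cue trials per session, tone/light
  cues with at most two consecutive presentations of the same modality, and
  inter-trial intervals of 60 +/- 45 s.
* In-vitro calibration beaker series: 250 uM ascorbate, cumulative 20/40/60 uM
  glutamate, and 2 uM dopamine additions with plateau shifts proportional to
  electrode sensitivity.
* Pavlovian conditioned approach (PCA) sessions of 25 lever-CS trials with
  phenotype-dependent lever/food-port behavior.

All generators are deterministic given (config, seed): identical inputs yield
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PhenotypeParams",
    "ElectrodeParams",
    "GeneratorConfig",
    "SessionSchedule",
    "CalibrationSeriesData",
    "transient_pulse",
    "gen_cttt_session",
    "gen_glutamate_trace",
    "gen_cue_window",
    "gen_calibration_series",
    "gen_pca_sessions",
    "write_trace",
    "write_event_log",
    "write_calibration_series",
]

PHENOTYPES = ("GT", "ST")

#: Cue is on for 2 s; treadmill stops 1 s after cue offset and restarts after
#: a 5 s pause, i.e. 8 s after cue onset.
CUE_DURATION_S = 2.0
TREADMILL_STOP_S = 3.0
PAUSE_S = 5.0
TRIAL_SPAN_S = 8.0
#: Reward lands on average 3.6 s after cue offset, jittered +/- 1 s.
REWARD_DELAY_MEAN_S = 3.6
REWARD_DELAY_JITTER_S = 1.0

ITI_MIN_S = 15.0
ITI_MAX_S = 105.0
TRIALS_PER_SESSION = 18

PCA_TRIALS_PER_SESSION = 25
PCA_CS_DURATION_S = 8.0


@dataclass(frozen=True)
class PhenotypeParams:
    """Per-phenotype parameters of the behavioral / neurochemical generator.

    Amplitudes are in uM glutamate (concentration at the electrode), latencies
    and times in seconds relative to the anchoring event.
    """

    single_peak_prob: float
    peak_amplitude_mean: float
    peak_amplitude_sd: float
    extra_peak_latency_means: tuple[float, float] = (1.58, 1.83)
    extra_peak_latency_sds: tuple[float, float] = (0.39, 0.25)
    reward_peak_amplitude_mean: float = 4.0
    reward_peak_amplitude_sd: float = 1.5
    reward_peak_prob: float = 0.7
    turn_prob: float = 0.7
    stop_prob: float = 0.9
    turn_initiation_mean: float = 1.5
    turn_initiation_sd: float = 0.7
    turn_duration_mean: float = 2.5
    turn_duration_sd: float = 0.5
    first_peak_latency_mean: float = 0.5
    first_peak_latency_sd: float = 0.15
    #: Among multi-peak traces, probability of a third peak (vs exactly two).
    third_peak_prob: float = 0.4

    def validate(self) -> None:
        for name in ("single_peak_prob", "reward_peak_prob", "turn_prob",
                     "stop_prob", "third_peak_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.peak_amplitude_mean <= 0:
            raise ValueError("peak_amplitude_mean must be positive")


@dataclass(frozen=True)
class ElectrodeParams:
    """In-vitro electrode characteristics used to synthesize currents.

    Defaults are the mean measured values of the accepted electrodes:
    sensitivity 12.0 pA/uM, glutamate:AA selectivity 113.1:1, and a dopamine
    response of 0.26 pA to the 2 uM dopamine addition.
    """

    sensitivity: float = 12.0          # pA per uM glutamate
    aa_selectivity: float = 113.1      # glutamate:AA sensitivity ratio
    da_response: float = 0.26          # pA at the 2 uM dopamine addition

    def validate(self) -> None:
        if self.sensitivity < 0:
            raise ValueError("sensitivity must be non-negative")
        if self.aa_selectivity <= 0:
            raise ValueError("aa_selectivity must be positive")
        if self.da_response < 0:
            raise ValueError("da_response must be non-negative")


def _default_phenotypes() -> dict[str, PhenotypeParams]:
    # GT: predominantly single, high cue-locked peaks; later turn initiation.
    # ST: 2-3 smaller cue-locked peaks (>80% of traces multi-peak), larger and
    # more reliable reward-locked peaks, faster turn initiation.
    return {
        "GT": PhenotypeParams(
            single_peak_prob=0.85,
            peak_amplitude_mean=8.5,
            peak_amplitude_sd=2.5,
            reward_peak_amplitude_mean=3.0,
            reward_peak_amplitude_sd=1.0,
            reward_peak_prob=0.5,
            turn_prob=0.75,
            stop_prob=0.9,
            turn_initiation_mean=1.8,
            turn_initiation_sd=0.8,
            turn_duration_mean=2.7,
            turn_duration_sd=0.5,
        ),
        "ST": PhenotypeParams(
            single_peak_prob=0.2,
            peak_amplitude_mean=6.0,
            peak_amplitude_sd=2.0,
            reward_peak_amplitude_mean=6.0,
            reward_peak_amplitude_sd=2.0,
            reward_peak_prob=0.9,
            turn_prob=0.65,
            stop_prob=0.9,
            turn_initiation_mean=1.3,
            turn_initiation_sd=0.6,
            turn_duration_mean=2.3,
            turn_duration_sd=0.5,
        ),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Top-level generator configuration.

    ``noise_sd`` is the marginal SD of per-channel current noise in pA; the
    default of 3.6 pA corresponds to 0.3 uM baseline noise after conversion
    at the default sensitivity of 12 pA/uM (no baseline noise SD in
    concentration units is reported for the recordings; this is a free
    parameter).  Channel noise is AR(1)-correlated (``noise_ar``), emulating
    the low-pass characteristic of the recording chain; at 5 Hz, white noise
    would make every slowly decaying supra-threshold tail sprout spurious
    single-sample prominences that the peak criteria count as peaks.
    """

    seed: int = 0
    sampling_rate: float = 5.0          # Hz
    noise_sd: float = 3.6               # pA, per channel
    noise_ar: float = 0.85              # AR(1) coefficient of channel noise
    drift_rate: float = 0.02            # pA/s, shared linear drift
    artifact_rate: float = 0.5          # events/min, shared rectangular pulses
    artifact_amplitude: float = 50.0    # pA
    artifact_duration: float = 1.0      # s
    background_current: float = 200.0   # pA, shared standing current
    pulse_rise: float = 0.3             # s, transient rise time constant scale
    pulse_decay: float = 1.0            # s, transient decay time constant
    phenotype_params: Mapping[str, PhenotypeParams] = field(
        default_factory=_default_phenotypes)
    electrode_params: ElectrodeParams = field(default_factory=ElectrodeParams)

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.noise_ar < 1.0:
            raise ValueError("noise_ar must be in [0, 1)")
        for params in self.phenotype_params.values():
            params.validate()
        self.electrode_params.validate()

    def params_for(self, phenotype: str) -> PhenotypeParams:
        if phenotype not in self.phenotype_params:
            raise ValueError(
                f"unknown phenotype {phenotype!r}; "
                f"expected one of {sorted(self.phenotype_params)}")
        return self.phenotype_params[phenotype]


@dataclass(frozen=True)
class SessionSchedule:
    """One CTTT session: ordered cue trials plus sampled outcomes.

    ``events`` is a tidy frame with one row per trial and columns
    trial, cue_onset_s, modality, role, outcome, turn_init_s, turn_complete_s,
    reward_s, stop_observed.  Times are absolute within the session; NaN marks
    absent events.
    """

    events: pd.DataFrame

    @property
    def n_trials(self) -> int:
        return len(self.events)

    @property
    def duration(self) -> float:
        return float(self.events["cue_onset_s"].iloc[-1] + TRIAL_SPAN_S + 20.0)


def _child_rng(seed: int, *keys: int) -> np.random.Generator:
    """Stable, collision-resistant child RNG from a root seed and keys."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=keys))


def _ar1_noise(rng: np.random.Generator, n: int, sd: float,
               phi: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal SD ``sd`` and lag-1 correlation
    ``phi``."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    innov = rng.normal(0.0, sd * np.sqrt(1.0 - phi * phi), n)
    innov[0] = rng.normal(0.0, sd)
    out = np.empty(n)
    acc = 0.0
    for i in range(n):
        acc = phi * acc + innov[i] if i else innov[0]
        out[i] = acc
    return out


def transient_pulse(t: np.ndarray, apex_time: float, amplitude: float,
                    rise: float = 0.3, decay: float = 1.0) -> np.ndarray:
    """Glutamate transient: linear rise to a cusp apex, exponential decay.

    The pulse reaches its maximum ``amplitude`` exactly at ``apex_time`` and
    is zero before ``apex_time - rise``.  The cusp at the apex is deliberate:
    released glutamate appears at the electrode over a fraction of a sample
    at 5 Hz, and a transient whose top is flat relative to the 0.2-s sample
    spacing cannot satisfy an immediate-neighbor prominence criterion
    whenever its apex falls between two samples.
    """
    if rise <= 0 or decay <= 0:
        raise ValueError("rise and decay must be positive")
    rel = t - apex_time
    shape = np.where(rel < 0,
                     np.clip(1.0 + rel / rise, 0.0, None),
                     np.exp(-np.clip(rel, 0.0, None) / decay))
    return amplitude * shape


def gen_cttt_session(config: GeneratorConfig, phenotype: str,
                     seed: int) -> SessionSchedule:
    """Generate one 18-trial CTTT session schedule with sampled outcomes.

    Cue modalities (tone/light) alternate pseudo-randomly with at most two
    consecutive trials of the same modality; half the cues of each modality
    carry the turn rule (tone = turn by convention here).  ITIs are uniform on
    [15, 105] s, the reading of the reported 60 +/- 45 s.
    """
    config.validate()
    params = config.params_for(phenotype)
    rng = _child_rng(seed, 1)

    modalities: list[str] = []
    for _ in range(TRIALS_PER_SESSION):
        if len(modalities) >= 2 and modalities[-1] == modalities[-2]:
            # forced alternation after two repeats
            modalities.append("light" if modalities[-1] == "tone" else "tone")
        else:
            modalities.append(rng.choice(["tone", "light"]))
    roles = ["turn" if m == "tone" else "stop" for m in modalities]

    itis = rng.uniform(ITI_MIN_S, ITI_MAX_S, size=TRIALS_PER_SESSION)
    onsets = np.empty(TRIALS_PER_SESSION)
    t = 30.0  # lead-in baseline walking period
    for i in range(TRIALS_PER_SESSION):
        t += itis[i]
        onsets[i] = t
        t += TRIAL_SPAN_S

    rows = []
    for i, (onset, modality, role) in enumerate(zip(onsets, modalities, roles)):
        turn_init = np.nan
        turn_complete = np.nan
        reward = np.nan
        stop_observed = False
        if role == "turn":
            if rng.random() < params.turn_prob:
                outcome = "cued_turn"
                init_lat = float(np.clip(
                    rng.normal(params.turn_initiation_mean,
                               params.turn_initiation_sd), 0.2, 8.0))
                duration = float(np.clip(
                    rng.normal(params.turn_duration_mean,
                               params.turn_duration_sd), 0.3, None))
                turn_init = onset + init_lat
                turn_complete = turn_init + duration
            else:
                outcome = "miss"
        else:
            if rng.random() < params.stop_prob:
                outcome = "cued_stop"
                stop_observed = True
            else:
                # the rare error mode on stop trials: a turn during the pause
                outcome = "false_turn"
                turn_init = onset + TREADMILL_STOP_S + float(
                    rng.uniform(0.3, PAUSE_S - 0.5))
                turn_complete = turn_init + float(np.clip(
                    rng.normal(params.turn_duration_mean,
                               params.turn_duration_sd), 0.3, None))
        if outcome in ("cued_turn", "cued_stop"):
            reward = onset + CUE_DURATION_S + float(np.clip(
                rng.normal(REWARD_DELAY_MEAN_S, REWARD_DELAY_JITTER_S / 2),
                REWARD_DELAY_MEAN_S - REWARD_DELAY_JITTER_S,
                REWARD_DELAY_MEAN_S + REWARD_DELAY_JITTER_S))
        rows.append({
            "trial": i,
            "cue_onset_s": onset,
            "modality": modality,
            "role": role,
            "outcome": outcome,
            "turn_init_s": turn_init,
            "turn_complete_s": turn_complete,
            "reward_s": reward,
            "stop_observed": stop_observed,
        })
    return SessionSchedule(events=pd.DataFrame(rows))


#: Minimum apex separation (s) for two transients to remain resolvable as
#: distinct peaks at 5 Hz given the ~1 s decay of the pulse shape.
MIN_PEAK_SEPARATION_S = 0.5


def _draw_cue_apexes(rng: np.random.Generator, params: PhenotypeParams,
                     max_latency: float = 3.2) -> list[float]:
    """Apex latencies (s from cue onset) for one cue-locked transient group.

    Multi-peak draws anchor the first transient tightly to cue onset
    (N(0.4, 0.1) clipped to [0.2, 0.7]) so later apexes, drawn from the
    secondary-latency distributions, are rarely rejected by the resolvability
    constraint; single-peak draws use the phenotype's first-peak latency.
    """
    multi = rng.random() >= params.single_peak_prob
    if multi:
        first = float(np.clip(rng.normal(0.4, 0.1), 0.2, 0.7))
    else:
        first = float(np.clip(
            rng.normal(params.first_peak_latency_mean,
                       params.first_peak_latency_sd), 0.2, 1.0))
    apexes = [first]
    if multi:
        n_extra = 2 if rng.random() < params.third_peak_prob else 1
        for k in range(n_extra):
            mean = params.extra_peak_latency_means[k]
            sd = params.extra_peak_latency_sds[k]
            lo = apexes[-1] + MIN_PEAK_SEPARATION_S
            lat = float(rng.normal(mean, sd))
            tries = 0
            while not (lo <= lat <= max_latency) and tries < 100:
                lat = float(rng.normal(mean, sd))
                tries += 1
            if tries >= 100:
                lat = float(np.clip(lat, lo, max_latency))
            apexes.append(lat)
    return apexes


def _draw_amplitude(rng: np.random.Generator, mean: float, sd: float) -> float:
    return float(np.clip(rng.normal(mean, sd), 1.0, None))


def gen_glutamate_trace(schedule: SessionSchedule, config: GeneratorConfig,
                        phenotype: str, seed: int,
                        align_to_grid: bool = False,
                        electrode_id: str = "E00"):
    """Synthesize the dual-channel current trace for one CTTT session.

    Shared components (standing current, linear drift, rectangular artifact
    pulses) enter both channels; glutamate transients (converted to pA via the
    electrode sensitivity) enter the active channel only.  Per-channel white
    noise is independent, so active - sentinel recovers the injected
    transients exactly in the noiseless limit.

    ``align_to_grid`` snaps transient apexes to the 5 Hz sample grid, which
    makes injected amplitudes exactly recoverable (used by recovery tests).

    Returns a :class:`neurogluflow.traces.DualChannelTrace`.
    """
    from .traces import DualChannelTrace, TraceMetadata

    config.validate()
    if schedule.n_trials == 0:
        raise ValueError("schedule must contain at least one trial")
    params = config.params_for(phenotype)
    ep = config.electrode_params
    rng = _child_rng(seed, 2)

    fs = config.sampling_rate
    duration = schedule.duration
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    if schedule.events["cue_onset_s"].max() + TRIAL_SPAN_S > duration:
        raise ValueError("schedule events extend beyond the trace duration")

    shared = config.background_current + config.drift_rate * t
    n_artifacts = rng.poisson(config.artifact_rate * duration / 60.0)
    artifact_times = np.sort(rng.uniform(0.0, duration, size=n_artifacts))
    for at in artifact_times:
        mask = (t >= at) & (t < at + config.artifact_duration)
        shared = shared + config.artifact_amplitude * mask

    conc = np.zeros(n)  # injected glutamate, uM
    for row in schedule.events.itertuples():
        apexes = _draw_cue_apexes(rng, params)
        for k, apex in enumerate(apexes):
            amp = _draw_amplitude(
                rng, params.peak_amplitude_mean * (1.0 if k == 0 else 0.7),
                params.peak_amplitude_sd * (1.0 if k == 0 else 0.7))
            apex_abs = row.cue_onset_s + apex
            if align_to_grid:
                apex_abs = round(apex_abs * fs) / fs
            conc += transient_pulse(t, apex_abs, amp,
                                    config.pulse_rise, config.pulse_decay)
        if np.isfinite(row.reward_s) and rng.random() < params.reward_peak_prob:
            amp = _draw_amplitude(rng, params.reward_peak_amplitude_mean,
                                  params.reward_peak_amplitude_sd)
            apex_abs = row.reward_s + float(np.clip(
                rng.normal(0.5, 0.15), 0.2, 1.0))
            if align_to_grid:
                apex_abs = round(apex_abs * fs) / fs
            conc += transient_pulse(t, apex_abs, amp,
                                    config.pulse_rise, config.pulse_decay)

    active = (shared + ep.sensitivity * conc
              + _ar1_noise(rng, n, config.noise_sd, config.noise_ar))
    sentinel = shared + _ar1_noise(rng, n, config.noise_sd, config.noise_ar)

    meta = TraceMetadata(
        electrode_id=electrode_id,
        sampling_rate=fs,
        da_response=ep.da_response,
        calibration_ref=None,
        qc_flags={},
    )
    return DualChannelTrace(time=t, active=active, sentinel=sentinel,
                            metadata=meta)


def gen_cue_window(config: GeneratorConfig, phenotype: str, seed: int,
                   n_peaks: int | None = None,
                   window_duration: float = 3.5,
                   baseline_duration: float = 2.5):
    """Synthesize a single cue-anchored concentration window plus baseline.

    Convenience generator for peak-detection studies: returns
    ``(baseline_values, window_values, apex_latencies, amplitudes)`` in uM on
    the 5 Hz grid, with the cue at t = 0.  ``n_peaks`` forces the number of
    cue-locked transients (``None`` samples it from ``single_peak_prob``).
    """
    config.validate()
    params = config.params_for(phenotype)
    rng = _child_rng(seed, 3)
    fs = config.sampling_rate
    noise_um = config.noise_sd / max(config.electrode_params.sensitivity, 1e-12)

    if n_peaks is None:
        apexes = _draw_cue_apexes(rng, params)
    else:
        forced = replace(params, single_peak_prob=0.0 if n_peaks > 1 else 1.0,
                         third_peak_prob=1.0 if n_peaks >= 3 else 0.0)
        apexes = _draw_cue_apexes(rng, forced)
    amps = [_draw_amplitude(
        rng, params.peak_amplitude_mean * (1.0 if k == 0 else 0.7),
        params.peak_amplitude_sd * (1.0 if k == 0 else 0.7))
        for k in range(len(apexes))]

    n_base = int(np.floor(baseline_duration * fs))
    n_win = int(np.floor(window_duration * fs))
    t = np.arange(n_win) / fs
    window = np.zeros(n_win)
    for apex, amp in zip(apexes, amps):
        window += transient_pulse(t, apex, amp,
                                  config.pulse_rise, config.pulse_decay)
    window += _ar1_noise(rng, n_win, noise_um, config.noise_ar)
    baseline = _ar1_noise(rng, n_base, noise_um, config.noise_ar)
    return baseline, window, apexes, amps


DEFAULT_ADDITIONS = (
    ("AA", 250.0),
    ("glutamate", 20.0),
    ("glutamate", 40.0),
    ("glutamate", 60.0),
    ("dopamine", 2.0),
)


@dataclass(frozen=True)
class CalibrationSeriesData:
    """Synthetic four-channel calibration series with its addition log."""

    time: np.ndarray
    currents: dict[str, np.ndarray]
    site_roles: dict[str, str]
    additions: tuple[tuple[str, float, float], ...]  # analyte, final uM, time


def gen_calibration_series(
        electrode_params: ElectrodeParams | None = None,
        noise_sd: float = 1.2,
        seed: int = 0,
        additions: Sequence[tuple[str, float]] = DEFAULT_ADDITIONS,
        baseline_duration: float = 60.0,
        step_interval: float = 60.0,
        sampling_rate: float = 5.0,
        settle_tau: float = 2.0,
        sentinel_interferent_factor: float = 1.0) -> CalibrationSeriesData:
    """Synthesize an in-vitro calibration beaker series.

    Two glutamate-sensing sites respond to glutamate at ``sensitivity`` pA/uM,
    to ascorbate at ``sensitivity / aa_selectivity`` pA/uM, and to the 2 uM
    dopamine addition with ``da_response`` pA.  Two sentinel sites carry the
    interferent (AA/dopamine) responses only.  Steps approach their plateaus
    with a short mixing time constant; white noise of ``noise_sd`` pA is added
    per site.
    """
    ep = electrode_params or ElectrodeParams()
    ep.validate()
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = _child_rng(seed, 4)

    glut_concs = [c for a, c in additions if a == "glutamate"]
    if glut_concs != sorted(glut_concs) or len(set(glut_concs)) != len(glut_concs):
        raise ValueError("glutamate additions must be strictly increasing")

    total = baseline_duration + step_interval * len(additions)
    n = int(round(total * sampling_rate))
    t = np.arange(n) / sampling_rate

    addition_log = []
    glut = np.zeros(n)
    aa = np.zeros(n)
    da = np.zeros(n)
    cum = {"glutamate": 0.0, "AA": 0.0, "dopamine": 0.0}
    for i, (analyte, final_conc) in enumerate(additions):
        at = baseline_duration + i * step_interval
        addition_log.append((analyte, float(final_conc), float(at)))
        delta = final_conc - cum[analyte]
        if delta < 0:
            raise ValueError("final concentrations must be non-decreasing")
        cum[analyte] = final_conc
        step = np.where(t >= at, 1.0 - np.exp(-np.clip(t - at, 0, None)
                                              / settle_tau), 0.0)
        if analyte == "glutamate":
            glut = glut + delta * step
        elif analyte == "AA":
            aa = aa + delta * step
        else:
            da = da + delta * step

    aa_sens = ep.sensitivity / ep.aa_selectivity          # pA/uM ascorbate
    da_per_um = ep.da_response / 2.0                      # pA/uM dopamine
    interferent = aa_sens * aa + da_per_um * da

    currents: dict[str, np.ndarray] = {}
    roles: dict[str, str] = {}
    for site in ("active_1", "active_2"):
        currents[site] = (ep.sensitivity * glut + interferent
                          + rng.normal(0, noise_sd, n))
        roles[site] = "active"
    for site in ("sentinel_1", "sentinel_2"):
        currents[site] = (sentinel_interferent_factor * interferent
                          + rng.normal(0, noise_sd, n))
        roles[site] = "sentinel"

    return CalibrationSeriesData(time=t, currents=currents, site_roles=roles,
                                 additions=tuple(addition_log))


# ---------------------------------------------------------------------------
# PCA sessions
# ---------------------------------------------------------------------------

_PCA_BEHAVIOR = {
    # (lever contact prob/trial, mean lever contacts given contact,
    #  lever latency mean, port entry prob/trial, mean port entries,
    #  port latency mean)
    "GT": (0.10, 1.2, 4.0, 0.90, 2.5, 1.5),
    "ST": (0.90, 2.5, 1.5, 0.10, 1.2, 4.0),
    "IN": (0.50, 1.8, 3.0, 0.50, 1.8, 3.0),
}


def gen_pca_sessions(phenotype: str, n_sessions: int, seed: int,
                     rat_id: str = "R00",
                     preset: str | None = None) -> pd.DataFrame:
    """Generate PCA trial records: 25 CS trials per session.

    ``preset`` overrides the stochastic model with deterministic extremes:
    ``"pure_ST"`` (a lever contact at CS onset on every trial, never the food
    port) or ``"pure_GT"`` (the reverse).  Latencies of absent responses are
    recorded as NaN; session scoring applies the 8-s cap.
    """
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    if preset is None and phenotype not in _PCA_BEHAVIOR:
        raise ValueError(f"unknown phenotype {phenotype!r}")
    if preset is not None and preset not in ("pure_ST", "pure_GT"):
        raise ValueError(f"unknown preset {preset!r}")
    rng = _child_rng(seed, 5)

    rows = []
    for session in range(1, n_sessions + 1):
        for trial in range(1, PCA_TRIALS_PER_SESSION + 1):
            if preset == "pure_ST":
                lever, lever_lat, port, port_lat = 1, 0.0, 0, np.nan
                iti_entries = 0
            elif preset == "pure_GT":
                lever, lever_lat, port, port_lat = 0, np.nan, 1, 0.0
                iti_entries = 0
            else:
                (p_lever, mu_lever, lat_lever,
                 p_port, mu_port, lat_port) = _PCA_BEHAVIOR[phenotype]
                lever = (rng.poisson(mu_lever - 1) + 1
                         if rng.random() < p_lever else 0)
                port = (rng.poisson(mu_port - 1) + 1
                        if rng.random() < p_port else 0)
                lever_lat = (float(np.clip(rng.exponential(lat_lever),
                                           0.0, PCA_CS_DURATION_S))
                             if lever else np.nan)
                port_lat = (float(np.clip(rng.exponential(lat_port),
                                          0.0, PCA_CS_DURATION_S))
                            if port else np.nan)
                iti_entries = int(rng.poisson(1.0))
            rows.append({
                "rat_id": rat_id, "session": session, "trial": trial,
                "lever_contacts": lever, "lever_latency_s": lever_lat,
                "cs_port_entries": port, "port_latency_s": port_lat,
                "iti_port_entries": iti_entries,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# File dialects
# ---------------------------------------------------------------------------

def write_trace(trace, path: Path | str) -> None:
    """Write a trace as CSV (time_s, active_pA, sentinel_pA) + JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame({"time_s": trace.time, "active_pA": trace.active,
                       "sentinel_pA": trace.sentinel})
    df.to_csv(path, index=False, float_format="%.6f")
    meta = {
        "electrode_id": trace.metadata.electrode_id,
        "sampling_rate": trace.metadata.sampling_rate,
        "da_response": trace.metadata.da_response,
        "calibration_ref": trace.metadata.calibration_ref,
        "qc_flags": trace.metadata.qc_flags,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def write_event_log(schedule: SessionSchedule, path: Path | str) -> None:
    schedule.events.to_csv(path, index=False, float_format="%.4f")


def write_calibration_series(series: CalibrationSeriesData,
                             path: Path | str) -> None:
    """Write currents CSV plus a ``*_additions.csv`` addition log."""
    path = Path(path)
    df = pd.DataFrame({"time_s": series.time})
    for site, cur in series.currents.items():
        df[site] = cur
    df.to_csv(path, index=False, float_format="%.6f")
    add = pd.DataFrame(series.additions,
                       columns=["analyte", "final_concentration_uM", "time_s"])
    add.to_csv(path.with_name(path.stem + "_additions.csv"), index=False)
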