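# Methods

## Scope and model

The package re-implements, as a tested pipeline over synthetic data, an
analysis chain for fixed-potential amperometry of striatal glutamate during
cued treadmill behavior: electrode calibration, sentinel-corrected
conversion of currents to concentration, event-locked peak detection,
Pavlovian-approach phenotyping, cued-turning scoring, and
contingency-table statistics on peak-conditioned turn probabilities.

The measurement model is linear: a glutamate-oxidase-coated recording site
produces current `I = S·c + I_shared + ε`, where `S` is the calibration
sensitivity (pA/µM), `c` the glutamate concentration at the electrode, and
`I_shared` background shared with an enzyme-free sentinel site on the same
shank (standing current, drift, electrostatic artifacts). Subtracting the
sentinel leaves `S·c + ε'`; division by the calibration slope yields µM.
For electrodes with a dopamine response above 0.1 pA the net current is
divided by that response to correct for variation in the interferent
exclusion layer; the conversion slope is rescaled by the same factor, so
the resulting concentration is invariant to whether normalization was
applied (one of two defensible readings of the normalization step; it is
the one that keeps concentrations comparable across electrodes, and it is
configurable via the `da_response` argument of `to_concentration`).

## Peak definition

A sample in a cue- or reward-anchored window is a peak if it exceeds the
trial's baseline mean + 3 SD (baseline = 2.5 s pre-cue) and its immediately
preceding and subsequent samples both lie at least 1 SD below it. A maximal
run of two or more adjacent supra-threshold samples containing no such peak
and spanning less than 1 SD contributes its highest sample (earliest on
ties) as one peak — without this rule a sustained elevation would yield no
peak at all, since none of its samples is bordered on both sides by values
1 SD lower.

Two boundary conventions are deliberate and resolved toward fewer peaks:
the 3 SD threshold is strict and the drop condition is `≤ value − 1 SD`;
the adjacent-run rescue requires at least two samples (a singleton
candidate that fails the drop test is not a peak). The pre-window side of
the first sample is baseline by construction and therefore satisfies the
drop; the post-window side of the last sample is evaluated on the
continuing trace when the caller supplies it, else the edge satisfies the
drop. Peak apexes are sample-aligned; no sub-sample interpolation is
attempted at 5 Hz. Degenerate noiseless baselines (SD = 0) are floored at
machine epsilon and flagged, which keeps thresholding defined while making
any nonzero excursion supra-threshold.

An interpretive note: the prominence condition tests the *immediately
adjacent* samples, not the minima between neighboring peaks. This is the
reading under which the adjacent-run rule is ever needed (its stated
purpose is to rescue runs in which no sample is bordered on both sides by
values 1 SD below), and the test suite pins it with a brute-force
per-sample oracle over thousands of randomized windows.

## Synthetic-data generator

The generator is the package's stand-in for animal data and defines the
study conditions; its defaults are fixed, not tuned per analysis.

* **Sampling**: 5 Hz, two channels; shared standing current 200 pA, linear
  drift 0.02 pA/s, rectangular shared artifacts (0.5/min, 50 pA, 1 s).
* **Noise**: per-channel AR(1) with marginal SD 3.6 pA (= 0.3 µM at the
  default sensitivity; no baseline noise SD is reported for the recordings,
  so this is a free parameter) and lag-1 correlation 0.85. The correlation
  models the low-pass characteristic of the electrochemical recording
  chain. It is not cosmetic: with white noise at 5 Hz, every slowly
  decaying supra-threshold tail acquires single-sample noise prominences at
  a rate of order 20% per sample *independent of the noise scale* (the
  required 1 SD jump and the noise SD cancel), which would make the
  published peak criteria unusable on any data — clearly not the regime
  they were applied in.
* **Transients**: linear rise (0.3 s) to a cusp apex, exponential decay
  (1 s), amplitude in µM. The cusp is equally load-bearing: a pulse whose
  top is flat relative to the 0.2-s sample spacing cannot satisfy an
  immediate-neighbor prominence criterion whenever its apex straddles two
  samples. Physically, terminal depolarization delivers glutamate to the
  electrode over well under one sample at 5 Hz.
* **Phenotype structure** (per-label parameters, chosen once from the
  reported contrasts): GT cue-locked transients are predominantly single
  (`single_peak_prob = 0.85`) and large (amplitude 8.5 ± 2.5 µM);
  ST transients are multiple in 80% of traces (`single_peak_prob = 0.2`;
  third peak in 40% of multi-peak traces) and smaller (6.0 ± 2.0 µM), with
  second/third apex latencies drawn from N(1.58, 0.39²) and N(1.83, 0.25²)
  seconds after cue onset — the reported second-peak latency statistics.
  Reward-locked transients are more reliable and larger in STs (90%,
  6 ± 2 µM) than GTs (50%, 3 ± 1 µM). Turn probabilities 0.75 (GT) / 0.65
  (ST); stop probability 0.9; turn initiation 1.8 ± 0.8 s (GT) / 1.3 ±
  0.6 s (ST) with durations 2.7 / 2.3 s.
* **Multi-peak resolvability**: secondary apexes are redrawn until they are
  at least 0.5 s after the previous apex and inside the 3.2-s analysis
  span (≈2.5% of draws; expected mean shift ≈ +0.02 s). Multi-peak first
  apexes sit at 0.4 ± 0.1 s so that the secondary-latency distribution is
  minimally truncated.
* **Sessions**: 18 cue trials, tone/light with at most two consecutive
  same-modality cues, ITI uniform on [15, 105] s (the stated 60 ± 45 s; the
  distribution is not named, uniform is assumed), reward 3.6 s ± 1 s after
  cue offset on rewarded trials. Trial outcomes are Bernoulli draws from
  the phenotype parameters with no trial-history dependence. PCA sessions
  are 25 lever-CS trials; the `pure_ST` / `pure_GT` presets produce the
  deterministic extreme sessions that pin the index at ±1.
* **Calibration series**: 60-s baseline, additions every 60 s (AA 250 µM,
  glutamate to 20/40/60 µM, dopamine 2 µM), 2-s mixing time constant;
  electrode defaults at the mean measured quality (12.0 pA/µM, 113.1:1,
  0.26 pA dopamine response).

Everything is seeded through `numpy.random.SeedSequence` spawn keys;
identical (config, seed) gives byte-identical outputs, file outputs
included.

### What the generator does not emulate

No diffusion/uptake biophysics, no enzyme kinetics or sensor drift in
sensitivity, no video or kinematics, no trial-history effects, no
within-phenotype coupling between glutamate amplitude and trial outcome
(outcomes and amplitudes are conditionally independent given phenotype, so
synthetic relative-probability curves reflect the phenotype turn-rate
contrast, not an amplitude dose-response), and no electrode-to-electrode
heterogeneity beyond the configurable parameters. Passing tests therefore
demonstrate that the pipeline recovers what the generator injects under
realistic noise — not that the biological effect sizes would be recovered
from arbitrary real recordings.

## Window conventions

Windows are half-open `[anchor, anchor + duration)` with the anchor snapped
to the nearest sample at or after the event time; sample counts are
`floor(duration × rate)` (12 baseline, 10 cue, 10 reward samples at 5 Hz).
The baseline window ends at the cue-onset sample exclusive, so no post-cue
sample influences baseline statistics (pinned by a no-look-ahead test).
Cue and reward windows are baseline-corrected by their own trial's baseline
mean. Events whose windows do not fit in the trace are skipped and logged,
not fatal.

The second-peak latency analysis detects peaks on an extended 3.5-s
cue-anchored window: the N(1.58, 0.39²) latency distribution puts ≈14% of
second apexes beyond the 2-s cue period, and truncating at 2 s would bias
the recovered mean by about −0.10 s. The standard 2-s cue window is used
everywhere else; note this means the within-cue-period peak *count*
undercounts late second peaks by construction — a tension already present
in the published design, where the counting window is 2 s but the reported
second-peak latencies extend past it.

The recovered second-peak latency carries a small, stable positive bias
(≈ +0.07 s at n = 500: ≈ +0.03 from the resolvability truncation, ≈ +0.01
from selective loss of closely spaced pairs, ≈ +0.03 from apex rounding on
an asymmetric pulse), comfortably inside the ±0.1 s recovery tolerance; it
is reported here rather than compensated.

## Statistics

Fisher's exact test (two-sided, probability-mass convention) and the
Pearson chi-square are delegated to scipy behind the module surface and
verified in the tests against a full hypergeometric enumeration and the
closed-form 2×2 statistic respectively. The Koopman asymptotic-score
interval for the ratio of two binomial proportions is implemented here: for
each candidate ratio ρ the constrained MLE of the second proportion solves
the profile-likelihood quadratic, the score chi-square is the sum of the
two binomial score terms, and the 95% bounds are the roots of
`χ²(ρ) = χ²₀.₉₅,₁`, found by bisection in log ρ outward from the point
estimate (a grid-inversion oracle pins the endpoints to 10⁻⁴ in the tests;
empirical coverage over 2,000 simulated pairs is 94.2% at n = 100 per
group). Degenerate tables (zero turns in a group) return one-sided
markers rather than numbers.

The threshold sweep conditions on `max_peak ≥ x` (the "≥" convention of
the figure axis labels; configurable) crossed with peak-count classes
(any / single / two-or-three); any condition with a contingency cell below
10 is flagged excluded and not interpreted. No multiple-testing correction
is applied within the sweep, matching the per-threshold reporting
convention; a Bonferroni pass can be applied downstream if desired.

Linear mixed-effects modelling, ANOVA, and post-hoc corrections are out of
scope by design: the pipeline emits tidy per-trace feature tables
(`peak_features.csv`) for any external statistics package.

## Calibration conventions

Plateaus are means over the final 10 s before the next addition (the
measurement interval after each solution is not specified; 10 s of a 60-s
settling period is comfortably post-transient). Glutamate shifts are
referenced to the plateau immediately preceding the first glutamate
addition so the ascorbate response cannot leak into the intercept-free
slope. LOD uses the 3σ/slope convention (no formula is stated in the
source protocol; this convention reproduces the reported magnitudes).
Linearity is evaluated as the correlation R (the criterion is stated as
R > 0.95) with R² also emitted; the stated 20–80 µM linearity range is
inconsistent with the 20/40/60 µM addition schedule, so the fit simply uses
whatever glutamate additions are present. The electrode-level dopamine
response is the largest plateau shift across glutamate-sensing sites,
which is conservative for the < 3 pA criterion.

## Behavioral scoring conventions

PCA latencies of absent responses enter session means at the 8-s CS
duration cap — the convention forced by the requirement that an animal
responding on every trial at latency zero scores exactly ±1. The response
bias of a session with no CS-period responses of either kind is defined as
0 (behaviorally neutral). Classification-band boundaries ±0.5 are
inclusive toward GT/ST. The 90° body-rotation judgment behind a logged
turn is treated as an input; scoring applies only the timing rules
(initiation within 8 s of cue onset, inclusive; a turn during the 5-s pause
of a stop trial is a false turn). "70% correct responses to either cue" is
read as both cue types ≥ 70% on two consecutive sessions. Stop trials with
neither a stop nor a turn logged are emitted as `unclassified` rather than
guessed.

## Problem sizes

Defaults throughout were chosen as the smallest sizes at which the checked
statistics stabilize: 500 windows for latency recovery, ≥1,000 random
windows for the detector/oracle equivalence, 2,000 simulated pairs for
interval coverage, 600–800 windows per phenotype for sweep demonstrations,
and a 4+4-rat, 2-session cohort for the end-to-end drivers.

## Known limitations

* The detector inherits the published criteria's resolution limit: peaks
  closer than ≈0.5 s at 5 Hz merge, and amplitudes are quantized to the
  sample grid (up to ≈10% low for an apex falling mid-bin).
* The calibration fit assumes plateau stationarity; it does not model
  sensor run-down within a series.
* Synthetic relative-probability curves encode the phenotype contrast
  through turn rates only (see generator non-goals above).
* QC exclusion flags (artifacts, task non-compliance, electrode placement)
  are accepted as inputs and applied, not inferred from the signal.
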