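# neurogluflow

Analysis pipeline for **event-locked glutamate amperometry in behaving
animals**: from raw dual-channel biosensor currents and behavioral trial
logs to phenotype-stratified, event-locked glutamate peak statistics and
relative turn-probability curves.

The pipeline targets the experimental design in which rats screened as
**sign-trackers (ST)** or **goal-trackers (GT)** by a Pavlovian conditioned
approach (PCA) test perform a cue-triggered turning task (CTTT) on a
treadmill while extracellular glutamate is measured in the dorsomedial
striatum with glutamate-oxidase microelectrode arrays sampled at 5 Hz.
Because the animal recordings themselves are not distributed with this
package, a first-class synthetic-data module generates calibration series,
dual-channel current traces, and behavioral session logs with the
statistical structure the analyses assume, so every downstream stage is
tested end to end.

## What the pipeline computes

1. **Electrode calibration** (`neurogluflow.calibration`) — from an in-vitro
   addition series (250 µM ascorbate; glutamate to 20/40/60 µM; 2 µM
   dopamine): sensitivity *S* (pA/µM, intercept-free least squares on
   plateau shifts), linearity *R*, limit of detection `LOD = 3·σ_baseline/S`,
   glutamate:AA selectivity, and dopamine response, with pass/fail flags
   against the acceptance criteria (*S* > 5 pA/µM, *R* > 0.95, LOD < 1 µM,
   selectivity > 50:1, dopamine response < 3 pA).
2. **Trace processing** (`neurogluflow.traces`) — sentinel-channel
   subtraction, dopamine normalization (applied when the electrode's
   dopamine response exceeds 0.1 pA), conversion to µM glutamate via the
   calibration slope, and extraction of per-trial baseline (2.5 s pre-cue),
   cue (2 s), and reward (2 s) windows, each baseline-corrected by its own
   trial's baseline mean.
3. **Peak detection** (`neurogluflow.peaks`) — the 3-criterion definition:
   a peak must exceed baseline mean + 3 SD; its neighboring samples must lie
   at least 1 SD below it; and a run of adjacent supra-threshold samples
   within 1 SD of each other contributes its highest sample as one peak.
   Features per window: maximum peak (µM), number of peaks, time to peak.
4. **Behavioral scoring** (`neurogluflow.pca`, `neurogluflow.cttt`) — the
   PCA index (mean of probability difference, response bias, and latency
   score, each in [−1, 1]) with GT/IN/ST classification at ∓0.5 on the
   session 4–5 average; CTTT outcomes (cued turn within 8 s / miss / cued
   stop / false turn) and the ≥70%-for-two-sessions learning criterion.
5. **Contingency statistics** (`neurogluflow.stats`) — threshold-conditioned
   2×2 turn/miss tables by phenotype, Fisher exact p, the relative turn
   probability RR = (GT turns/GT total)/(ST turns/ST total) with its 95%
   **Koopman asymptotic-score interval** (score-test inversion for a ratio
   of binomial proportions), Pearson chi-square for peak-count frequency
   tables, and the n < 10 cell-count exclusion rule.

## Worked example

Run the numbered drivers in order (they write under `results/`):

```bash
python analysis/01_simulate_cohort.py     # synthetic cohort raw data
python analysis/02_fit_calibration.py     # electrode acceptance
python analysis/03_process_traces.py      # currents -> peak features
python analysis/04_phenotype_behavior.py  # PCA + CTTT scoring
python analysis/05_second_peak_latency.py # ST second-peak structure
python analysis/06_threshold_sweep.py     # relative turn probabilities
```

`02_fit_calibration.py` prints, for the synthetic electrode lot generated at
the mean measured quality:

```
  sensitivity :   12.00 pA/uM   (criterion > 5.0)
  linearity R :  1.0000        (criterion > 0.95)
  LOD         :   0.304 uM      (criterion < 1.0)
  selectivity :   114.1 : 1    (criterion > 50.0)
  DA response :   0.522 pA     (criterion < 3.0)
  -> passed all criteria: True
```

`03_process_traces.py` recovers the phenotype contrast in peak counts —
goal-trackers predominantly single cue-locked peaks, sign-trackers two or
three — and quantifies it:

```
            1   2  >=3  no_peak
GT         59   6    0        8
ST         23  39    5        5
chi-square(2, N = 132) = 44.98, p = 1.705e-10
```

`05_second_peak_latency.py` checks that the detector recovers the
sign-tracker second-peak latency the generator injects (mean 1.58 s):

```
detected second-apex mean : 1.650 s (target 1.58 s, tolerance +/-0.1 s)
```

`06_threshold_sweep.py` prints the relative-probability table; e.g. on the
single-peak curve the GT:ST relative turn probability rises from 1.23 at
≥2 µM to 1.57 at ≥8 µM (95% Koopman interval 1.13–2.53), meaning a GT was
about one and a half times as likely as an ST to turn when a single
high-amplitude glutamate peak followed the turn cue.

A `neurogluflow` console command exposes the same stages
(`generate`, `calibrate`, `score-session`, `pca`, `sweep`, `run-all`), e.g.
`neurogluflow run-all --seed 7 --out results/run`.

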