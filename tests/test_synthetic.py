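"""Generator determinism, schedule constraints, and construction guarantees."""

import numpy as np
import pandas as pd
import pytest

from neurogluflow import synthetic
from neurogluflow.synthetic import (
    ElectrodeParams,
    GeneratorConfig,
    gen_calibration_series,
    gen_cttt_session,
    gen_cue_window,
    gen_glutamate_trace,
    gen_pca_sessions,
    transient_pulse,
)


class TestCTTTSession:
    def test_default_session_has_18_trials(self, config):
        sched = gen_cttt_session(config, "GT", seed=1)
        assert sched.n_trials == 18

    def test_same_seed_gives_identical_event_logs(self, config):
        a = gen_cttt_session(config, "ST", seed=5).events
        b = gen_cttt_session(config, "ST", seed=5).events
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_phenotype_rejected(self, config):
        with pytest.raises(ValueError, match="phenotype"):
            gen_cttt_session(config, "XX", seed=0)

    @pytest.mark.parametrize("phenotype", ["GT", "ST"])
    def test_schedule_constraints_over_many_seeds(self, config, phenotype):
        # >10,000 generated trials: no 3-run of one modality, ITIs in bounds
        for seed in range(600):
            ev = gen_cttt_session(config, phenotype, seed=seed).events
            m = ev["modality"].tolist()
            assert not any(m[i] == m[i + 1] == m[i + 2]
                           for i in range(len(m) - 2))
            onsets = ev["cue_onset_s"].to_numpy()
            gaps = np.diff(onsets) - synthetic.TRIAL_SPAN_S
            assert gaps.min() >= synthetic.ITI_MIN_S - 1e-9
            assert gaps.max() <= synthetic.ITI_MAX_S + 1e-9

    def test_outcomes_consistent_with_roles(self, config):
        ev = pd.concat([gen_cttt_session(config, "GT", seed=s).events
                        for s in range(50)])
        turn = ev[ev.role == "turn"]
        stop = ev[ev.role == "stop"]
        assert set(turn.outcome) <= {"cued_turn", "miss"}
        assert set(stop.outcome) <= {"cued_stop", "false_turn"}
        # cued turns always carry initiation within the 8-s bound
        turns = turn[turn.outcome == "cued_turn"]
        lat = turns.turn_init_s - turns.cue_onset_s
        assert (lat > 0).all() and (lat <= 8.0).all()


class TestGlutamateTrace:
    def test_noiseless_no_event_difference_is_zero(self, quiet_config):
        sched = gen_cttt_session(quiet_config, "GT", seed=2)
        trace = gen_glutamate_trace(sched, quiet_config, "GT", seed=3)
        net = trace.active - trace.sentinel
        # away from events the net holds only vanishing transient tails
        far = np.ones(len(trace.time), dtype=bool)
        for onset in sched.events.cue_onset_s:
            far &= ~((trace.time > onset - 5) & (trace.time < onset + 25))
        assert far.sum() > 100
        assert np.allclose(net[far], 0.0, atol=1e-4)
        # and nowhere is the net negative beyond numerical dust
        assert net.min() > -1e-9

    def test_shared_artifacts_cancel_in_subtraction(self, quiet_config):
        import dataclasses
        cfg = dataclasses.replace(quiet_config, artifact_rate=10.0)
        sched = gen_cttt_session(cfg, "GT", seed=4)
        trace = gen_glutamate_trace(sched, cfg, "GT", seed=5)
        # same config with artifacts of zero amplitude: identical RNG draws,
        # so the injected transients coincide and the nets must match
        flat = dataclasses.replace(cfg, artifact_amplitude=0.0)
        quiet = gen_glutamate_trace(sched, flat, "GT", seed=5)
        assert not np.allclose(trace.active, quiet.active)  # artifacts exist
        assert np.allclose(trace.active - trace.sentinel,
                           quiet.active - quiet.sentinel, atol=1e-9)

    def test_same_seed_identical_traces(self, config):
        sched = gen_cttt_session(config, "ST", seed=6)
        a = gen_glutamate_trace(sched, config, "ST", seed=7)
        b = gen_glutamate_trace(sched, config, "ST", seed=7)
        assert np.array_equal(a.active, b.active)
        assert np.array_equal(a.sentinel, b.sentinel)

    def test_multi_peak_fraction_matches_single_peak_prob(self, config):
        # single_peak_prob 0.2 -> ~80% of ST cue windows carry 2-3 transients
        n_multi = 0
        n = 1000
        for i in range(n):
            _, _, apexes, _ = gen_cue_window(config, "ST", seed=i)
            assert 1 <= len(apexes) <= 3
            n_multi += len(apexes) >= 2
        frac = n_multi / n
        assert abs(frac - 0.8) < 3 * np.sqrt(0.8 * 0.2 / n)

    def test_transient_pulse_peaks_at_apex_with_amplitude(self):
        t = np.linspace(0, 10, 5001)
        pulse = transient_pulse(t, apex_time=3.0, amplitude=7.5)
        assert pulse.max() == pytest.approx(7.5)
        assert t[pulse.argmax()] == pytest.approx(3.0, abs=2e-3)
        assert pulse[t < 2.69].max() == 0.0


class TestCalibrationSeries:
    def test_noiseless_plateau_shifts_are_linear(self):
        ep = ElectrodeParams(sensitivity=12.0)
        series = gen_calibration_series(ep, noise_sd=0.0, seed=0)
        t = series.time
        for site in ("active_1", "active_2"):
            cur = series.currents[site]
            # plateau after AA addition is the reference for glutamate steps
            ref = cur[(t >= 110) & (t < 120)].mean()
            for conc, t_end in [(20, 180), (40, 240), (60, 300)]:
                shift = cur[(t >= t_end - 10) & (t < t_end)].mean() - ref
                assert shift == pytest.approx(12.0 * conc, rel=1e-3)

    def test_sentinel_sites_do_not_respond_to_glutamate(self):
        series = gen_calibration_series(ElectrodeParams(), noise_sd=0.0, seed=0)
        t = series.time
        for site in ("sentinel_1", "sentinel_2"):
            cur = series.currents[site]
            pre = cur[(t >= 110) & (t < 120)].mean()
            post = cur[(t >= 290) & (t < 300)].mean()
            assert post - pre == pytest.approx(0.0, abs=1e-6)

    def test_zero_sensitivity_yields_flat_glutamate_response(self):
        series = gen_calibration_series(ElectrodeParams(sensitivity=0.0),
                                        noise_sd=0.0, seed=0)
        cur = series.currents["active_1"]
        t = series.time
        pre = cur[(t >= 110) & (t < 120)].mean()
        post = cur[(t >= 290) & (t < 300)].mean()
        assert post - pre == pytest.approx(0.0, abs=1e-6)

    def test_negative_sensitivity_rejected(self):
        with pytest.raises(ValueError):
            gen_calibration_series(ElectrodeParams(sensitivity=-1.0))

    def test_same_seed_identical_series(self):
        a = gen_calibration_series(seed=9)
        b = gen_calibration_series(seed=9)
        for site in a.currents:
            assert np.array_equal(a.currents[site], b.currents[site])


class TestPCASessions:
    def test_default_session_has_25_trials(self):
        df = gen_pca_sessions("GT", n_sessions=1, seed=0)
        assert len(df) == 25

    def test_pure_st_preset(self):
        df = gen_pca_sessions("ST", n_sessions=2, seed=0, preset="pure_ST")
        assert (df.lever_contacts >= 1).all()
        assert (df.cs_port_entries == 0).all()
        assert (df.lever_latency_s == 0.0).all()

    def test_pure_gt_preset(self):
        df = gen_pca_sessions("GT", n_sessions=1, seed=0, preset="pure_GT")
        assert (df.lever_contacts == 0).all()
        assert (df.cs_port_entries >= 1).all()

    def test_bad_session_count_rejected(self):
        with pytest.raises(ValueError):
            gen_pca_sessions("GT", n_sessions=0, seed=0)

    def test_deterministic(self):
        a = gen_pca_sessions("ST", 3, seed=11)
        b = gen_pca_sessions("ST", 3, seed=11)
        pd.testing.assert_frame_equal(a, b)


def test_config_validation_rejects_bad_probabilities():
    from neurogluflow.synthetic import PhenotypeParams
    with pytest.raises(ValueError, match="in \\[0, 1\\]"):
        PhenotypeParams(single_peak_prob=1.5, peak_amplitude_mean=5,
                        peak_amplitude_sd=1).validate()
    with pytest.raises(ValueError):
        GeneratorConfig(sampling_rate=0.0).validate()
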