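"""Peak detection: hand-traced examples, brute-force oracle equivalence, and
parameter-recovery properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neurogluflow.peaks import (
    BaselineStats,
    PeakSet,
    classify_peak_count,
    detect_peaks,
    peak_features,
)
from neurogluflow.synthetic import GeneratorConfig, gen_cue_window


def oracle_peaks(values, mean, sd, tail=None):
    """Direct per-sample transliteration of the three written criteria.

    Independent of the implementation's vectorized scan: every sample is
    tested on its own; runs are found by walking the window.
    """
    values = list(map(float, values))
    n = len(values)
    thr = mean + 3.0 * sd
    prominent = []
    for i in range(n):
        if not values[i] > thr:
            continue
        before_ok = True if i == 0 else values[i - 1] <= values[i] - sd
        if i < n - 1:
            after_ok = values[i + 1] <= values[i] - sd
        elif tail:
            after_ok = tail[0] <= values[i] - sd
        else:
            after_ok = True
        if before_ok and after_ok:
            prominent.append(i)
    result = list(prominent)
    i = 0
    while i < n:
        if values[i] > thr:
            j = i
            while j + 1 < n and values[j + 1] > thr:
                j += 1
            run = list(range(i, j + 1))
            if (len(run) >= 2
                    and not any(k in prominent for k in run)):
                seg = [values[k] for k in run]
                if max(seg) - min(seg) < sd:
                    result.append(run[int(np.argmax(seg))])
            i = j + 1
        else:
            i += 1
    return sorted(result)


B01 = BaselineStats(0.0, 1.0)


class TestExamples:
    @pytest.mark.parametrize("window,n_expected,max_expected,rule", [
        ([0, 0, 0, 0, 0], 0, None, None),
        ([0, 0.5, 4.0, 0.5, 0], 1, 4.0, "prominence"),
        ([0, 4.0, 3.5, 4.2, 0.2], 1, 4.2, "adjacent_run"),
        ([0, 4.0, 0.5, 5.0, 0], 2, 5.0, "prominence"),
    ])
    def test_hand_traced_windows(self, window, n_expected, max_expected,
                                 rule):
        ps = detect_peaks(np.array(window, dtype=float), B01)
        assert ps.n_peaks == n_expected
        assert ps.max_peak == max_expected
        if rule is not None:
            assert ps.peaks[-1].rule_used == rule

    def test_sustained_elevation_outside_run_range_gives_no_peak(self):
        # supra-threshold run spanning more than 1 SD, no 1-SD drop between
        # adjacent samples: neither rule 2 nor rule 3 applies
        ps = detect_peaks(np.array([0, 5.0, 4.3, 3.5, 0.0]), B01)
        assert ps.n_peaks == 0

    def test_tie_resolves_to_earliest_sample(self):
        ps = detect_peaks(np.array([0, 4.0, 4.0, 0.0]), B01)
        assert ps.n_peaks == 1
        assert ps.peaks[0].index == 1

    def test_tail_controls_last_sample_drop(self):
        rising = np.array([0, 0, 0, 0, 5.0])
        assert detect_peaks(rising, B01).n_peaks == 1
        assert detect_peaks(rising, B01,
                            tail=np.array([4.8])).n_peaks == 0

    def test_empty_window_and_bad_sd_rejected(self):
        with pytest.raises(ValueError):
            detect_peaks(np.array([]), B01)
        with pytest.raises(ValueError):
            detect_peaks(np.zeros(5), BaselineStats(0.0, 0.0))


class TestOracleEquivalence:
    def test_random_windows_match_oracle(self, rng):
        # mixed amplitudes around the 3-SD threshold exercise every branch
        for _ in range(1500):
            n = int(rng.integers(3, 12))
            base = rng.normal(0, 1, n)
            spikes = rng.random(n) < 0.4
            base[spikes] += rng.uniform(1.0, 7.0, int(spikes.sum()))
            ps = detect_peaks(base, B01)
            assert [p.index for p in ps.peaks] == oracle_peaks(base, 0.0, 1.0)

    @settings(max_examples=300, derandomize=True)
    @given(st.lists(st.floats(min_value=-2.0, max_value=8.0), min_size=1,
                    max_size=12),
           st.floats(min_value=0.3, max_value=2.0))
    def test_hypothesis_windows_match_oracle(self, window, sd):
        values = np.asarray(window)
        ps = detect_peaks(values, BaselineStats(0.0, sd))
        assert [p.index for p in ps.peaks] == oracle_peaks(window, 0.0, sd)

    def test_constant_offset_invariance_after_correction(self, rng):
        # adding an offset to baseline and window (then re-correcting, as the
        # window extractor does) leaves the peak set unchanged
        w = rng.normal(0, 1, 10)
        w[4] += 6.0
        a = detect_peaks(w, B01)
        b = detect_peaks((w + 2.5) - 2.5, B01)
        assert [p.index for p in a.peaks] == [p.index for p in b.peaks]


class TestFeatures:
    def test_empty_peakset_yields_missing_markers(self):
        feats = peak_features(PeakSet(peaks=[]))
        assert feats["max_peak_uM"] is None
        assert feats["n_peaks"] == 0
        assert feats["time_to_max_s"] is None

    def test_two_peak_features(self):
        ps = detect_peaks(np.array([0, 0, 4.0, 0.5, 0, 0, 5.0, 0.2]), B01)
        feats = peak_features(ps)
        assert feats["n_peaks"] == 2
        assert feats["max_peak_uM"] == pytest.approx(5.0)
        assert feats["time_to_max_s"] == pytest.approx(6 * 0.2)

    def test_single_peak_time_to_max_is_apex_time(self):
        ps = detect_peaks(np.array([0, 0, 4.0, 0.5]), B01)
        assert peak_features(ps)["time_to_max_s"] == ps.peaks[0].apex_time_rel


class TestRecovery:
    def test_noiseless_single_peak_amplitude_recovered(self, quiet_config):
        # grid-aligned apex: detected max equals the injected amplitude
        import dataclasses
        from neurogluflow.synthetic import transient_pulse

        fs = 5.0
        t = np.arange(0, 3.5, 1 / fs)
        window = transient_pulse(t, apex_time=0.6, amplitude=8.0)
        ps = detect_peaks(window, BaselineStats(0.0, 1e-9), dt=1 / fs)
        assert ps.max_peak == pytest.approx(8.0, abs=1e-9)

    def test_off_grid_apex_within_one_sample_quantization(self):
        from neurogluflow.synthetic import transient_pulse
        fs = 5.0
        t = np.arange(0, 3.5, 1 / fs)
        window = transient_pulse(t, apex_time=0.69, amplitude=8.0)
        ps = detect_peaks(window, BaselineStats(0.0, 1e-9), dt=1 / fs)
        assert ps.n_peaks == 1
        # worst-case quantization: one sample away on either flank
        lo = 8.0 * min(1 - 0.1 / 0.3, np.exp(-0.1))
        assert lo <= ps.max_peak <= 8.0

    def test_second_peak_latency_recovered(self, config):
        lats = []
        for i in range(500):
            base, win, _, _ = gen_cue_window(config, "ST", seed=i, n_peaks=2)
            bs = BaselineStats(0.0, float(np.std(base, ddof=1)))
            ps = detect_peaks(win, bs, dt=0.2)
            if ps.n_peaks >= 2:
                lats.append(ps.peaks[1].apex_time_rel)
        assert len(lats) > 300
        mean = float(np.mean(lats))
        target = config.params_for("ST").extra_peak_latency_means[0]
        assert abs(mean - target) <= 0.1


class TestClassifyPeakCount:
    def test_all_single_peaks(self):
        import pandas as pd
        df = pd.DataFrame({"phenotype": ["GT"] * 5, "n_peaks": [1] * 5})
        table = classify_peak_count(df)
        assert table.loc["GT", "1"] == 5
        assert table.loc["GT", "2"] == 0

    def test_category_totals_conserved(self, rng):
        import pandas as pd
        n = rng.integers(0, 5, 200)
        df = pd.DataFrame({"phenotype": ["ST"] * 200, "n_peaks": n})
        table = classify_peak_count(df)
        assert (table.loc["ST", ["1", "2", ">=3"]].sum()
                == (n >= 1).sum())
        assert table.loc["ST", "no_peak"] == (n == 0).sum()

    def test_st_generator_multi_peak_fraction(self, config):
        import pandas as pd
        counts = []
        for i in range(500):
            _, _, apexes, _ = gen_cue_window(config, "ST", seed=i)
            counts.append(len(apexes))
        df = pd.DataFrame({"phenotype": ["ST"] * 500, "n_peaks": counts})
        table = classify_peak_count(df)
        multi = table.loc["ST", "2"] + table.loc["ST", ">=3"]
        frac = multi / 500
        assert abs(frac - 0.8) < 3 * np.sqrt(0.8 * 0.2 / 500)
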