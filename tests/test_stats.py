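"""Contingency statistics: enumeration oracles, interval coverage, and sweep
symmetries."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from neurogluflow.stats import (
    CHI2_95,
    ContingencyTable2x2,
    _koopman_chi2,
    fisher_exact,
    koopman_rr_ci,
    pearson_chi_square,
    threshold_sweep,
)


def fisher_oracle(a, b, c, d):
    """Full hypergeometric enumeration of the two-sided probability-mass p."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    lo, hi = max(0, col1 - row2), min(col1, row1)
    probs = {x: hypergeom.pmf(x, n, col1, row1) for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7))


class TestFisher:
    def test_balanced_table_p_is_one(self):
        assert fisher_exact(ContingencyTable2x2(5, 5, 5, 5)) \
            == pytest.approx(1.0)

    def test_two_by_two_hand_enumeration(self):
        # margins 2/2/2/2: tables x=0,1,2 have probs 1/6, 4/6, 1/6
        assert fisher_exact(ContingencyTable2x2(2, 0, 0, 2)) \
            == pytest.approx(1 / 3)

    def test_transposition_symmetry(self):
        t = ContingencyTable2x2(9, 3, 5, 11)
        transposed = ContingencyTable2x2(9, 5, 3, 11)
        assert fisher_exact(t) == pytest.approx(fisher_exact(transposed))

    def test_matches_enumeration_oracle_up_to_n200(self, rng):
        for _ in range(150):
            a, b, c, d = rng.integers(0, 50, size=4)
            if (a + c == 0) or (b + d == 0) or (a + b == 0) or (c + d == 0):
                continue
            t = ContingencyTable2x2(int(a), int(b), int(c), int(d))
            assert fisher_exact(t) == pytest.approx(
                fisher_oracle(a, b, c, d), rel=1e-6)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4).validate()


class TestKoopman:
    def test_equal_proportions_interval_contains_one(self):
        res = koopman_rr_ci(ContingencyTable2x2(10, 10, 10, 10))
        assert res.rr == pytest.approx(1.0)
        assert res.ci_low < 1.0 < res.ci_high

    def test_aggregate_turn_counts_ratio(self):
        # 206/318 turns vs 158/230 turns -> ratio ~0.943
        res = koopman_rr_ci(ContingencyTable2x2(206, 112, 158, 72))
        assert res.rr == pytest.approx(0.943, abs=5e-4)
        assert res.ci_low < res.rr < res.ci_high

    @pytest.mark.parametrize("cells", [
        (206, 112, 158, 72), (15, 5, 8, 12), (30, 2, 20, 15), (3, 17, 9, 11),
    ])
    def test_interval_matches_grid_inversion(self, cells):
        t = ContingencyTable2x2(*cells)
        res = koopman_rr_ci(t)
        grid = np.exp(np.linspace(math.log(1e-3), math.log(1e3), 240001))
        chi = np.array([_koopman_chi2(t.gt_turns, t.gt_total, t.st_turns,
                                      t.st_total, g) for g in grid])
        inside = grid[chi <= CHI2_95]
        assert res.ci_low == pytest.approx(inside[0], abs=1e-4 * inside[0]
                                           + 1e-4)
        assert res.ci_high == pytest.approx(inside[-1], abs=1e-4 * inside[-1]
                                            + 1e-4)

    def test_reciprocal_table_inverts_interval(self):
        t = ContingencyTable2x2(15, 5, 8, 12)
        a = koopman_rr_ci(t)
        b = koopman_rr_ci(t.swapped())
        assert b.rr == pytest.approx(1 / a.rr)
        assert b.ci_low == pytest.approx(1 / a.ci_high, rel=1e-6)
        assert b.ci_high == pytest.approx(1 / a.ci_low, rel=1e-6)

    def test_zero_st_turns_marked_one_sided(self):
        res = koopman_rr_ci(ContingencyTable2x2(5, 5, 0, 10))
        assert res.one_sided
        assert math.isinf(res.ci_high)

    def test_empirical_coverage_near_nominal(self):
        # 2,000 simulated binomial pairs at a known true ratio of 1.25
        rng = np.random.default_rng(12345)
        n1 = n2 = 100
        p1, p2 = 0.5, 0.4
        true = p1 / p2
        hits = 0
        reps = 2000
        for _ in range(reps):
            x1 = int(rng.binomial(n1, p1))
            x2 = int(rng.binomial(n2, p2))
            res = koopman_rr_ci(
                ContingencyTable2x2(x1, n1 - x1, x2, n2 - x2))
            hits += res.ci_low <= true <= res.ci_high
        assert abs(hits / reps - 0.95) <= 0.015


class TestChiSquare:
    def test_equal_rows_statistic_zero(self):
        stat, df, p = pearson_chi_square([[10, 20, 30], [10, 20, 30]])
        assert stat == pytest.approx(0.0)
        assert df == 2
        assert p == pytest.approx(1.0)

    def test_closed_form_2x2(self):
        stat, df, _ = pearson_chi_square([[30, 10], [10, 30]])
        assert stat == pytest.approx(20.0)
        assert df == 1

    def test_hand_computed_2x3(self):
        stat, df, _ = pearson_chi_square([[60, 30, 10], [20, 50, 30]])
        assert stat == pytest.approx(35.0)
        assert df == 2

    def test_permutation_invariance(self, rng):
        obs = rng.integers(1, 40, size=(3, 4))
        stat, _, _ = pearson_chi_square(obs)
        stat_p, _, _ = pearson_chi_square(obs[::-1, ::-1])
        assert stat_p == pytest.approx(stat)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi_square([[0, 0], [5, 5]])


def feature_frame(rng, n_per=400, gt_shift=0.0):
    rows = []
    for phen, shift in (("GT", gt_shift), ("ST", 0.0)):
        amp = rng.gamma(4.0, 1.2, n_per) + shift
        n_peaks = rng.integers(1, 4, n_per)
        turn = rng.random(n_per) < 0.6
        for a, k, t in zip(amp, n_peaks, turn):
            rows.append({"phenotype": phen, "outcome":
                         "turn" if t else "miss", "max_peak_uM": a,
                         "n_peaks": int(k)})
    return pd.DataFrame(rows)


class TestSweep:
    def test_null_features_give_rr_near_one(self, rng):
        df = feature_frame(rng, n_per=2000)
        sweep = threshold_sweep(df, thresholds=[1.0, 3.0],
                                peak_classes=("any",))
        included = sweep[sweep.included]
        assert (np.abs(np.log(included.rr)) < 0.25).all()

    def test_counts_non_increasing_in_threshold(self, rng):
        df = feature_frame(rng)
        sweep = threshold_sweep(df, thresholds=[0.0, 2.0, 4.0, 6.0])
        for _, grp in sweep.groupby("peak_class"):
            counts = grp.sort_values("threshold_uM")["n_traces"].to_numpy()
            assert (np.diff(counts) <= 0).all()

    def test_label_swap_inverts_rr_and_preserves_p(self, rng):
        df = feature_frame(rng, gt_shift=1.0)
        swapped = df.assign(phenotype=df.phenotype.map(
            {"GT": "ST", "ST": "GT"}))
        a = threshold_sweep(df, thresholds=[1.0, 3.0])
        b = threshold_sweep(swapped, thresholds=[1.0, 3.0])
        ok = a.included & b.included
        assert np.allclose(b.rr[ok], 1 / a.rr[ok])
        assert np.allclose(b.p_fisher[ok], a.p_fisher[ok], rtol=1e-9)

    def test_min_cell_rule_excludes_small_conditions(self):
        df = pd.DataFrame({
            "phenotype": ["GT"] * 19 + ["ST"] * 20,
            "outcome": (["turn"] * 9 + ["miss"] * 10
                        + ["turn"] * 10 + ["miss"] * 10),
            "max_peak_uM": [5.0] * 39,
            "n_peaks": [1] * 39,
        })
        sweep = threshold_sweep(df, thresholds=[0.0], peak_classes=("any",))
        assert not sweep.included.iloc[0]     # gt_turns cell is 9

    def test_empty_features_rejected(self):
        with pytest.raises(ValueError):
            threshold_sweep(pd.DataFrame(), thresholds=[1.0])
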