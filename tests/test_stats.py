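"""Ratio normalization, paired tests, RM-ANOVA and Bonferroni follow-ups."""
import numpy as np
import pandas as pd
import pytest

from tapfatigue.stats import (
    analyze_group,
    followup_bonferroni,
    paired_height_test,
    rm_anova_periods,
    to_periods,
    to_ratio,
)


def _bin_table(values_low, values_high, index="RMS_ANT", participant="P01"):
    rows = []
    for b, v in enumerate(values_low, start=1):
        rows.append((participant, "LOW", index, b, v))
    for b, v in enumerate(values_high, start=1):
        rows.append((participant, "HIGH", index, b, v))
    return pd.DataFrame(rows, columns=["participant", "height", "index", "bin", "value"])


class TestToRatio:
    def test_default_policy_references_low_first_bin(self):
        df = _bin_table([2.0] * 10, [4.0] * 10)
        out = to_ratio(df)
        low = out[out.height == "LOW"]["value"].to_numpy()
        high = out[out.height == "HIGH"]["value"].to_numpy()
        assert np.allclose(low, 1.0)
        assert np.allclose(high, 2.0)  # height effect survives normalization

    def test_mf_policy_references_own_height(self):
        df = _bin_table([80.0] * 10, [70.0] * 10, index="MF_ANT")
        out = to_ratio(df)
        assert np.allclose(out["value"], 1.0)

    def test_constant_series_all_ones(self):
        df = _bin_table([3.3] * 10, [3.3] * 10)
        assert np.allclose(to_ratio(df)["value"], 1.0)

    def test_idempotent(self):
        df = _bin_table(list(np.linspace(2, 1, 10)), list(np.linspace(3, 2, 10)))
        once = to_ratio(df)
        twice = to_ratio(once)
        assert np.allclose(once["value"], twice["value"])

    def test_zero_reference_warns_nan(self):
        df = _bin_table([0.0] + [1.0] * 9, [1.0] * 10)
        with pytest.warns(UserWarning, match="zero"):
            out = to_ratio(df)
        assert out["value"].isna().all()


class TestPairedHeightTest:
    def test_identical_vectors(self):
        res = paired_height_test(np.ones(20), np.ones(20))
        assert res.statistic == 0.0
        assert res.p == 1.0
        assert not res.significant

    def test_matches_scipy(self, rng):
        low = rng.normal(1.0, 0.2, 50)
        high = low + rng.normal(0.1, 0.2, 50)
        from scipy.stats import ttest_rel
        t, p = ttest_rel(high, low)
        res = paired_height_test(low, high)
        assert res.statistic == pytest.approx(t)
        assert res.p == pytest.approx(p)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            paired_height_test(np.ones(5), np.ones(6))

    def test_power_one_sd_shift_180_pairs(self, rng):
        # planted mean shift of one within-pair SD: essentially always detected
        rejections = 0
        reps = 200
        for _ in range(reps):
            low = rng.normal(0, 1, 180)
            high = low + rng.normal(1.0, 1.0, 180)
            if paired_height_test(low, high).significant:
                rejections += 1
        assert rejections / reps > 0.99

    def test_type_one_error_calibrated(self, rng):
        reps = 600
        rejections = sum(
            paired_height_test(rng.normal(0, 1, 180), rng.normal(0, 1, 180)).significant
            for _ in range(reps))
        assert rejections / reps == pytest.approx(0.05, abs=0.03)


def _period_long(wide):
    s, p = wide.shape
    rows = []
    for i in range(s):
        for j in range(p):
            rows.append((f"S{i}", j + 1, wide[i, j]))
    return pd.DataFrame(rows, columns=["participant", "period", "value"])


class TestRmAnova:
    def test_identical_periods_f_zero(self):
        wide = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 5))
        res = rm_anova_periods(wide)
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_hand_decomposition_three_subject_toy(self):
        # manual two-way (subject x period) decomposition
        wide = np.array([[3.0, 4.0, 5.0], [2.0, 4.0, 6.0], [1.0, 3.0, 4.0]])
        grand = wide.mean()
        ss_p = 3 * np.sum((wide.mean(0) - grand) ** 2)
        ss_s = 3 * np.sum((wide.mean(1) - grand) ** 2)
        ss_e = np.sum((wide - grand) ** 2) - ss_p - ss_s
        f_manual = (ss_p / 2) / (ss_e / 4)
        res = rm_anova_periods(wide)
        assert res.statistic == pytest.approx(f_manual)

    def test_matches_statsmodels_anovarm(self, rng):
        from statsmodels.stats.anova import AnovaRM
        wide = rng.normal(0, 1, (8, 5)) + np.linspace(0, 0.5, 5)
        long = _period_long(wide)
        sm = AnovaRM(long, depvar="value", subject="participant",
                     within=["period"]).fit()
        res = rm_anova_periods(long)
        assert res.statistic == pytest.approx(
            float(sm.anova_table["F Value"].iloc[0]))
        assert res.p == pytest.approx(float(sm.anova_table["Pr > F"].iloc[0]))

    def test_planted_monotone_effect_detected(self, rng):
        detected = 0
        for _ in range(50):
            wide = rng.normal(0, 0.5, (18, 5)) + np.linspace(0, 1.0, 5)
            if rm_anova_periods(wide).significant:
                detected += 1
        assert detected / 50 > 0.95

    def test_subject_with_missing_period_dropped(self):
        wide = np.array([[1.0, 2.0, 3.0], [np.nan, 2.0, 3.0], [2.0, 3.0, 4.0]])
        res = rm_anova_periods(wide)
        complete = rm_anova_periods(wide[[0, 2]])
        assert res.statistic == pytest.approx(complete.statistic)


class TestFollowupBonferroni:
    def test_corrected_threshold(self):
        wide = np.random.default_rng(0).normal(0, 1, (10, 5))
        results = followup_bonferroni(wide, alpha=0.05, m=4)
        assert len(results) == 4
        assert all(r.alpha == pytest.approx(0.0125) for r in results)

    def test_no_flags_when_periods_identical_to_p1(self):
        wide = np.tile(np.random.default_rng(1).normal(0, 1, (10, 1)), (1, 5))
        results = followup_bonferroni(wide)
        assert not any(r.significant for r in results)

    def test_shift_only_in_p5_flags_only_p5(self, rng):
        hits = np.zeros(4)
        reps = 60
        for _ in range(reps):
            wide = rng.normal(0, 0.3, (18, 5))
            wide[:, 4] += 1.0
            flags = [r.significant for r in followup_bonferroni(wide)]
            hits += np.array(flags, dtype=float)
        rates = hits / reps
        assert rates[3] > 0.95  # P5 vs P1
        assert np.all(rates[:3] < 0.10)


class TestAnalyzeGroup:
    def test_full_chain_detects_planted_effects(self, rng):
        rows = []
        for pid in range(12):
            base = rng.normal(10, 0.5)
            for b in range(1, 11):
                trend = 0.15 * b
                rows.append((f"P{pid:02d}", "LOW", "KV_LA", b,
                             base + trend + rng.normal(0, 0.2)))
                rows.append((f"P{pid:02d}", "HIGH", "KV_LA", b,
                             base + trend + 2.0 + rng.normal(0, 0.2)))
        table = pd.DataFrame(rows, columns=["participant", "height", "index", "bin", "value"])
        res = analyze_group(table)
        height_row = res[res.comparison == "HIGH vs LOW"].iloc[0]
        assert height_row.significant
        anova_rows = res[res.comparison.str.contains("RM-ANOVA")]
        assert anova_rows.significant.all()
        followups = res[res.comparison.str.contains("P5 vs P1")]
        assert len(followups) == 2 and followups.significant.all()

    def test_periods_pool_pairs_of_bins(self):
        df = _bin_table(list(range(1, 11)), list(range(11, 21)))
        pooled = to_periods(df)
        low = pooled[pooled.height == "LOW"].sort_values("period")["value"].to_numpy()
        assert np.allclose(low, [1.5, 3.5, 5.5, 7.5, 9.5])
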