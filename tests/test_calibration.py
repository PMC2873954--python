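"""Detection curves, ID-50, regressions, variance partition, replication."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cghdiv import (
    AnalysisError,
    MAD_CONSISTENCY,
    call_diverged,
    detection_curve,
    find_crossover,
    fit_feature_stats,
    fit_id50,
    kinetics_regression,
    linreg_ratio_id,
    replication_power_analysis,
    robust_sd,
    shrink_variances,
    variance_partition,
)


def calls_frame(diverged, pct_id):
    """Minimal calls table for curve fitting."""
    idx = [f"F{i}" for i in range(len(diverged))]
    df = pd.DataFrame(
        {
            "mean_M": np.where(diverged, -1.0, 0.0),
            "q": 0.5,
            "diverged_q10": np.asarray(diverged, dtype=bool),
        },
        index=idx,
    )
    return df, pd.Series(np.asarray(pct_id, dtype=float), index=idx)


class TestDetectionCurve:
    def test_all_diverged_gives_unit_curve(self):
        calls, ids = calls_frame(np.ones(200, dtype=bool), np.linspace(70, 99, 200))
        curve = detection_curve(calls, ids, window=51)
        assert np.allclose(curve["frac_q10"], 1.0)

    def test_window_equal_to_n_gives_single_point(self):
        div = np.zeros(51, dtype=bool)
        div[:17] = True
        calls, ids = calls_frame(div, np.linspace(70, 99, 51))
        curve = detection_curve(calls, ids, window=51)
        assert len(curve) == 1
        assert curve["frac_q10"].iloc[0] == pytest.approx(17 / 51)

    def test_even_window_rejected(self):
        calls, ids = calls_frame(np.ones(100, dtype=bool), np.linspace(70, 99, 100))
        with pytest.raises(AnalysisError):
            detection_curve(calls, ids, window=50)

    def test_planted_step_recovered(self):
        # detection probability steps from 0.9 to 0.1 at 92 %ID
        rng = np.random.default_rng(17)
        ids = np.sort(rng.uniform(80, 100, 4000))
        div = rng.random(4000) < np.where(ids < 92, 0.9, 0.1)
        calls, id_s = calls_frame(div, ids)
        curve = detection_curve(calls, id_s, window=51)
        low = curve[curve["center_pct_id"] < 90]["frac_q10"].mean()
        high = curve[curve["center_pct_id"] > 94]["frac_q10"].mean()
        assert abs(low - 0.9) < 0.05
        assert abs(high - 0.1) < 0.05


class TestId50:
    def test_planted_midpoint_recovered(self):
        rng = np.random.default_rng(23)
        ids = rng.uniform(85, 100, 10000)
        p = 1.0 / (1.0 + np.exp(2.2 * (ids - 94.0)))  # true ID-50 = 94
        div = rng.random(10000) < p
        fit = fit_id50(div, ids)
        assert fit.status == "ok"
        assert abs(fit.id50 - 94.0) < 0.5
        assert fit.slope < 0

    def test_all_diverged_is_out_of_range_high(self):
        fit = fit_id50(np.ones(100), np.linspace(80, 99, 100))
        assert fit.status == "out_of_range_high"

    def test_none_diverged_is_out_of_range_low(self):
        fit = fit_id50(np.zeros(100), np.linspace(80, 99, 100))
        assert fit.status == "out_of_range_low"

    def test_complete_separation_reports_boundary(self):
        ids = np.concatenate([np.linspace(80, 89.9, 50), np.linspace(90.1, 99, 50)])
        div = (ids < 90).astype(float)
        fit = fit_id50(div, ids)
        assert fit.status in ("separation", "ok")
        assert abs(fit.id50 - 90.0) < 1.0

    def test_shift_invariance(self):
        rng = np.random.default_rng(29)
        ids = rng.uniform(85, 100, 5000)
        div = rng.random(5000) < 1.0 / (1.0 + np.exp(2.0 * (ids - 93.0)))
        base = fit_id50(div, ids)
        shifted = fit_id50(div, ids + 2.0)
        assert shifted.id50 - base.id50 == pytest.approx(2.0, abs=1e-6)


class TestLinReg:
    def test_exact_fit_on_noise_free_line(self):
        ids = np.linspace(70, 100, 500)
        m = -8.0 + 0.08 * ids
        res = linreg_ratio_id(m, ids)
        assert res.r2 == pytest.approx(1.0, abs=1e-12)
        assert res.slope == pytest.approx(0.08, abs=1e-10)

    def test_r2_equals_squared_pearson(self):
        rng = np.random.default_rng(31)
        ids = rng.uniform(70, 100, 2000)
        m = -8 + 0.08 * ids + rng.normal(0, 0.5, 2000)
        res = linreg_ratio_id(m, ids)
        assert res.r2 == pytest.approx(np.corrcoef(m, ids)[0, 1] ** 2, abs=1e-12)

    def test_shuffled_identity_has_no_signal(self):
        rng = np.random.default_rng(37)
        ids = rng.uniform(70, 100, 10000)
        m = -8 + 0.08 * ids + rng.normal(0, 0.3, 10000)
        res = linreg_ratio_id(m, rng.permutation(ids))
        assert res.r2 < 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(AnalysisError):
            linreg_ratio_id([0.0, 1.0, 2.0], [95.0, 95.0, 95.0])


def synth_kinetics(rng, n=2000, b_len=0.0, b_idgc=-0.05, noise=0.25):
    ids = rng.uniform(70, 100, n)
    gc = rng.normal(45, 8, n)
    length = rng.normal(500, 60, n)
    align = rng.normal(90, 8, n)
    z = lambda x: (x - x.mean()) / x.std()
    m = (
        -8 + 0.08 * ids + 0.1 * z(gc) + 0.05 * z(align)
        + b_len * z(length) + b_idgc * z(ids) * z(gc)
        + rng.normal(0, noise, n)
    )
    return m, ids, gc, length, align


class TestKineticsRegression:
    def test_negative_interaction_sign_recovered(self):
        rng = np.random.default_rng(41)
        m, ids, gc, length, align = synth_kinetics(rng, n=10000)
        res = kinetics_regression(m, ids, gc, length, align)
        assert res.table.loc["%ID:GC", "estimate"] < 0
        assert res.table.loc["%ID:GC", "p"] < 0.01

    def test_null_length_effect_is_usually_insignificant(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            m, ids, gc, length, align = synth_kinetics(rng, n=1000, b_len=0.0)
            res = kinetics_regression(m, ids, gc, length, align)
            hits += res.table.loc["length", "p"] > 0.05
        assert hits >= 90

    def test_standardized_fit_is_algebraically_equivalent(self):
        rng = np.random.default_rng(43)
        m, ids, gc, length, align = synth_kinetics(rng)
        raw = kinetics_regression(m, ids, gc, length, align, standardized=False)
        std = kinetics_regression(m, ids, gc, length, align, standardized=True)
        # both designs span the same space: fitted R^2 identical to 1e-8
        assert std.r2 == pytest.approx(raw.r2, abs=1e-8)

    def test_collinear_terms_are_named(self):
        rng = np.random.default_rng(47)
        ids = rng.uniform(70, 100, 500)
        with pytest.raises(AnalysisError, match="GC"):
            kinetics_regression(np.zeros(500), ids, ids, rng.normal(500, 60, 500),
                                rng.normal(90, 8, 500))

    def test_effect_profile_declines_with_identity(self):
        rng = np.random.default_rng(53)
        m, ids, gc, length, align = synth_kinetics(rng, n=10000, b_idgc=-0.05)
        std = kinetics_regression(m, ids, gc, length, align, standardized=True)
        prof = std.effect_profile("GC", np.array([75.0, 95.0]))
        assert prof["effect"].iloc[0] > prof["effect"].iloc[1]


class TestVariancePartition:
    def test_mad_scale_constant_matches_normal_quantile(self):
        assert abs(MAD_CONSISTENCY - stats.norm.ppf(0.75)) < 5e-5

    def test_mad_scale_is_consistent_for_normal_residuals(self):
        rng = np.random.default_rng(59)
        est = robust_sd(rng.normal(0, 0.3, 100000))
        assert abs(est - 0.3) / 0.3 < 0.02

    def test_noise_free_technical_is_zero(self):
        ids = np.linspace(70, 100, 400)
        vp = variance_partition(np.zeros(400), np.zeros(400), ids, window=301)
        assert np.allclose(vp["technical_sd"], 0.0)
        assert np.allclose(vp["kinetic_sd"], 0.0)

    def test_empty_bin_yields_nan(self):
        ids = np.concatenate([np.linspace(70, 75, 50), np.linspace(95, 99, 50)])
        vp = variance_partition(np.ones(100), np.ones(100), ids, bins=[70, 80, 90, 100])
        assert np.isnan(vp.loc[1, "technical_sd"])
        assert vp.loc[0, "n"] == 50

    def test_planted_crossover_is_recovered(self):
        # residual scale ramps up below 88 %ID, crossing the constant
        # technical SE of 0.15 at exactly 87 %ID
        rng = np.random.default_rng(61)
        n = 20000
        ids = np.sort(rng.uniform(75, 100, n))
        sd_k = 0.05 + 0.1 * np.clip(88.0 - ids, 0, None)
        resid = rng.normal(0, 1, n) * sd_k
        se = np.full(n, 0.15)
        vp = variance_partition(se, resid, ids, window=301)
        cross = find_crossover(vp)
        assert abs(cross - 87.0) < 0.5


class TestReplication:
    def test_full_combination_equals_whole_analysis(self, small_rm, pct_id):
        summary, se = replication_power_analysis(
            small_rm, pct_id, k_list=(8,), alpha=0.1, seed=0
        )
        stats_df = fit_feature_stats(small_rm)
        calls = call_diverged(shrink_variances(stats_df), thresholds=(0.1,))
        valid = calls["q"].notna() & pct_id.reindex(calls.index).notna()
        expect = 100.0 * calls.loc[valid, "diverged_q10"].mean()
        assert summary["n_combos"].iloc[0] == 1
        assert summary["pct_diverged"].iloc[0] == pytest.approx(expect, abs=1e-9)

    def test_more_arrays_reduce_fitted_se_everywhere(self, small_rm, pct_id):
        summary, se = replication_power_analysis(
            small_rm, pct_id, k_list=(2, 8), alpha=0.1, cap=15, seed=0
        )
        se_cols = [c for c in se.columns if c.startswith("se_bin_")]
        row2 = se[se["k"] == 2][se_cols].iloc[0]
        row8 = se[se["k"] == 8][se_cols].iloc[0]
        both = row2.notna() & row8.notna()
        assert both.any()
        assert (row8[both] < row2[both]).all()

    def test_power_grows_with_replication(self, small_rm, pct_id):
        summary, _ = replication_power_analysis(
            small_rm, pct_id, k_list=(2, 8), alpha=0.1, cap=15, seed=0
        )
        assert summary.set_index("k").loc[8, "pct_diverged"] >= summary.set_index("k").loc[2, "pct_diverged"]

    def test_k_exceeding_arrays_rejected(self, small_rm, pct_id):
        with pytest.raises(AnalysisError):
            replication_power_analysis(small_rm, pct_id, k_list=(10,))
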