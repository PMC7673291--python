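"""Trace fitting, lag detection, interpolation half-lives and the
production/degradation decomposition, against closed-form constructions."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

import sporelife as sl

LN2 = math.log(2.0)


def _trace(times_h, fold, baseline=1000.0, background=0.0, germ=None, bag="t"):
    return sl.TraceSeries(
        bag,
        np.asarray(times_h, float),
        background + baseline * np.asarray(fold, float),
        baseline_au=background + baseline,
        background_au=background,
        germination_time_h=germ,
    )


class TestTraceFit:
    def test_constant_trace_rate_zero(self):
        t = np.arange(0, 21, 1.0)
        fit = sl.fit_trace_exponential(_trace(t, np.ones_like(t)))
        assert fit.rate_per_h == 0.0
        assert fit.classification == "non_producing"

    def test_pure_exponential_exact(self):
        t = np.arange(0, 21, 1.0)
        fit = sl.fit_trace_exponential(_trace(t, np.exp(0.05 * t)))
        assert fit.rate_per_h == pytest.approx(0.05, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.classification == "producing"

    def test_lag_then_exponential_joint_fit(self):
        t = np.arange(0, 20.5, 0.5)
        fold = np.where(t < 8.0, 1.0, np.exp(0.05 * (t - 8.0)))
        fit = sl.fit_trace_exponential(_trace(t, fold))
        assert fit.rate_per_h == pytest.approx(0.05, abs=1e-10)
        assert fit.lag_h == pytest.approx(8.0, abs=0.5)

    def test_decaying_trace_negative_rate(self):
        t = np.arange(0, 21, 1.0)
        fit = sl.fit_trace_exponential(_trace(t, np.exp(-0.003 * t)))
        assert fit.rate_per_h == pytest.approx(-0.003, abs=1e-10)
        assert fit.classification == "non_producing"

    def test_truncated_at_germination(self):
        t = np.arange(0, 21, 1.0)
        fold = np.exp(0.05 * t)
        fold[t > 10] = 50.0  # garbage after germination must be ignored
        fit = sl.fit_trace_exponential(_trace(t, fold, germ=10.0))
        assert fit.rate_per_h == pytest.approx(0.05, abs=1e-10)

    def test_all_points_at_floor_zero_information(self):
        t = np.arange(0, 10, 1.0)
        trace = sl.TraceSeries(
            "f", t, np.full_like(t, 2500.0), baseline_au=3500.0, background_au=2500.0
        )
        fit = sl.fit_trace_exponential(trace)
        assert fit.flag == "zero_information"
        assert fit.classification == "non_producing"
        assert math.isnan(fit.rate_per_h)

    def test_unbiased_under_gaussian_noise(self):
        """Mean fitted rate over 200 noisy replicates sits within 3 SEs of
        the generative rate."""
        rng = np.random.default_rng(77)
        t = np.arange(0, 20, 1 / 6)
        rate_true, lag = 0.031, 6.0
        estimates = []
        for _ in range(200):
            signal = 1000.0 * np.where(t < lag, 1.0, np.exp(rate_true * (t - lag)))
            fluor = signal + rng.normal(0, 30.0, t.size)
            trace = sl.TraceSeries("n", t, fluor, baseline_au=1000.0)
            estimates.append(sl.fit_trace_exponential(trace).rate_per_h)
        err = np.mean(estimates) - rate_true
        se = np.std(estimates, ddof=1) / math.sqrt(len(estimates))
        assert abs(err) < max(3 * se, 0.001)

    def test_group_separation_on_defaults(self, config):
        """Dormant mean rate > 0 > dead mean rate, t-test p < 1e-3 at the
        study sizes (38 dormant + 32 dead)."""
        _, traces = sl.generate_trace_cohort(config, 38, 32, seed=123)
        fits = sl.fit_trace_cohort(traces)
        dorm = fits[fits.bag_id.str.startswith("dormant")].rate_per_h
        dead = fits[fits.bag_id.str.startswith("dead")].rate_per_h
        assert dorm.mean() > 0 > dead.mean()
        assert stats.ttest_ind(dorm, dead).pvalue < 1e-3


class TestDetectLag:
    def test_immediate_growth(self):
        t = np.arange(0, 10, 1.0)
        lag = sl.detect_lag(_trace(t, np.exp(0.2 * t)), noise_sd_au=0.0)
        assert lag == pytest.approx(t[1])  # first frame above the baseline value

    def test_flat_then_exponential(self):
        t = np.arange(0, 20, 1 / 6)
        fold = np.where(t < 8.0, 1.0, np.exp(0.1 * (t - 8.0)))
        lag = sl.detect_lag(_trace(t, fold), noise_sd_au=0.0)
        assert lag == pytest.approx(8.0, abs=1 / 6 + 1e-9)

    def test_never_exceeds_threshold(self):
        t = np.arange(0, 10, 1.0)
        assert sl.detect_lag(_trace(t, np.ones_like(t)), noise_sd_au=5.0) is None

    def test_short_trace_rejected(self):
        t = np.arange(0, 5, 1.0)
        with pytest.raises(ValueError, match="frames"):
            sl.detect_lag(_trace(t, np.ones_like(t)))

    def test_generated_lags_fall_in_configured_band(self, config):
        """Noise-free dormant traces: detected lag inside the generative
        5-10 h window (one frame of slack) for >= 95% of traces."""
        tp = replace(config.traces, noise_sd_au=0.0)
        cfg = replace(config, traces=tp)
        frame_h = cfg.traces.frame_interval_min / 60.0
        hits = total = 0
        for seed in range(5):
            _, traces = sl.generate_trace_cohort(cfg, 30, 0, seed=seed)
            for tr in traces:
                lag = sl.detect_lag(tr, noise_sd_au=0.0)
                total += 1
                if lag is not None and 5.0 - frame_h <= lag <= 10.0 + frame_h:
                    hits += 1
        assert hits / total >= 0.95


class TestHalfLife:
    def test_exact_sample_hit(self):
        curve = sl.DecayCurve([0.0, 7.0], [1.0, 0.5])
        assert sl.half_life_by_interpolation(curve) == (7.0, "interpolated")

    def test_interpolation_bias_small_and_positive(self):
        """Sampling an 8.4-day exponential every 2 days: the piecewise-linear
        crossing is slightly late (chord under a convex curve), within
        0.05 days."""
        t = np.arange(0, 15, 2.0)
        curve = sl.DecayCurve(t, np.exp(-LN2 * t / 8.4))
        est, flag = sl.half_life_by_interpolation(curve)
        assert flag == "interpolated"
        assert 0 < est - 8.4 < 0.05

    def test_converges_with_sampling_interval(self):
        for dt, tol in ((2.0, 0.05), (0.5, 0.005), (0.1, 0.0005)):
            t = np.arange(0, 15, dt)
            est, _ = sl.half_life_by_interpolation(
                sl.DecayCurve(t, np.exp(-LN2 * t / 8.4))
            )
            assert abs(est - 8.4) < tol

    def test_extrapolation_algebra(self):
        curve = sl.DecayCurve([0.0, 2.0], [1.0, 0.8])
        est, flag = sl.half_life_by_interpolation(curve)
        assert flag == "extrapolated"
        assert est == pytest.approx(5.0)

    def test_first_crossing_on_nonmonotone_curve(self):
        curve = sl.DecayCurve([0, 1, 2, 3], [1.0, 0.4, 0.6, 0.3])
        est, flag = sl.half_life_by_interpolation(curve)
        assert flag == "interpolated"
        assert 0 < est < 1  # crossing located in the first falling segment

    def test_increasing_curve_rejected(self):
        with pytest.raises(ValueError, match="cross"):
            sl.half_life_by_interpolation(sl.DecayCurve([0, 1, 2], [1.0, 1.1, 1.2]))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            sl.DecayCurve([0, 1], [1.0, np.nan])


class TestDecomposition:
    def test_printed_half_life_pair(self):
        """8.4-day inhibited vs 14-day drug-free half-lives give a ~30.3-day
        characteristic production time."""
        rates = sl.decompose_production(8.4, 14.0)
        assert rates.production_per_day == pytest.approx(
            LN2 * (1 / 8.4 - 1 / 14), rel=1e-12
        )
        assert rates.characteristic_production_time_days == pytest.approx(30.3, abs=0.05)

    def test_hand_arithmetic_pair(self):
        rates = sl.decompose_production(7.0, 14.0)
        assert rates.production_per_day == pytest.approx(LN2 / 14, rel=1e-12)
        assert rates.characteristic_production_time_days == pytest.approx(
            14 / LN2, rel=1e-12
        )

    def test_equal_half_lives_flag_infinite(self):
        rates = sl.decompose_production(10.0, 10.0)
        assert rates.production_per_day == 0.0
        assert math.isinf(rates.characteristic_production_time_days)
        assert rates.flag == "no_production"

    def test_inconsistent_pair_flagged(self):
        rates = sl.decompose_production(14.0, 8.4)
        assert rates.production_per_day < 0
        assert rates.flag == "inconsistent"

    def test_exact_inverse_of_two_exponential_generator(self):
        """Round trip to machine precision: generate noise-free decay curves
        from (p, d), measure half-lives densely, decompose back."""
        p, d = 0.021, 0.0825
        t = np.arange(0, 60, 0.001)
        h_inhib, _ = sl.half_life_by_interpolation(sl.DecayCurve(t, np.exp(-d * t)))
        h_nodrug, _ = sl.half_life_by_interpolation(
            sl.DecayCurve(t, np.exp(-(d - p) * t))
        )
        rates = sl.decompose_production(h_inhib, h_nodrug)
        assert rates.production_per_day == pytest.approx(p, rel=1e-5)
        assert rates.k_deg_per_day == pytest.approx(d, rel=1e-5)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            sl.decompose_production(0.0, 14.0)


class TestClassification:
    def test_germinated_is_dormant_regardless_of_fit(self):
        fit = sl.TraceFit("a", -0.01, None, 0.9, "non_producing", 50)
        call = sl.classify_dormant_dead(fit, True)
        assert call.label == "dormant"
        assert call.flag == "discordant"

    def test_dead_with_negative_rate_concordant(self):
        fit = sl.TraceFit("b", -0.003, None, 0.5, "non_producing", 50)
        call = sl.classify_dormant_dead(fit, False)
        assert call.label == "dead"
        assert call.concordant

    def test_dead_with_producing_trace_flagged(self):
        fit = sl.TraceFit("c", 0.03, 6.0, 0.95, "producing", 50)
        call = sl.classify_dormant_dead(fit, False)
        assert call.label == "dead"
        assert call.flag == "discordant"

    def test_missing_outcome_unlabeled(self):
        call = sl.classify_dormant_dead(None, None)
        assert call.label == "unlabeled"

    def test_short_horizon_rejected(self):
        with pytest.raises(ValueError):
            sl.classify_dormant_dead(None, True, horizon_h=12.0)
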