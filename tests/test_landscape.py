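"""Landscape estimation, dose-response fitting, minimum-glucose
log-regression and marker associations, against hand-computed and
closed-form oracles."""

import math
from dataclasses import replace

import numpy as np
import pytest
from sklearn.isotonic import IsotonicRegression

import sporelife as sl
from sporelife import SporeBagRecord


def _records(markers, germ, glucose=0.001):
    out = []
    for i, (m, g) in enumerate(zip(markers, germ)):
        out.append(
            SporeBagRecord(
                f"b{i}",
                glucose,
                bool(g),
                germination_time_min=100.0 if g else None,
                gfp_inducibility=float(m),
            )
        )
    return out


class TestBinProbability:
    def test_hand_enumeration(self):
        recs = _records([1, 1, 2, 2, 3, 3], [1, 0, 1, 1, 0, 0])
        res = sl.bin_probability(recs, bin_edges=[0.5, 1.5, 2.5, 3.5])
        assert np.allclose(res.prob, [0.5, 1.0, 0.0])
        assert np.array_equal(res.counts, [2, 2, 2])
        assert not res.reliable.any()  # all counts below the default minimum

    def test_all_germinated_gives_ones(self):
        recs = _records(np.linspace(1, 10, 30), np.ones(30))
        res = sl.bin_probability(recs, bin_edges=np.linspace(0, 11, 5))
        filled = ~np.isnan(res.prob)
        assert np.all(res.prob[filled] == 1.0)

    def test_non_monotone_edges_rejected(self):
        recs = _records([1, 2], [1, 0])
        with pytest.raises(ValueError):
            sl.bin_probability(recs, bin_edges=[0, 2, 1])

    def test_unbiased_for_bernoulli_mean(self, rng):
        """Binned estimate sits within 3 binomial SEs of the generative p."""
        p_true = 0.3
        n = 4000
        markers = rng.uniform(1, 2, n)
        germ = rng.random(n) < p_true
        recs = _records(markers, germ)
        res = sl.bin_probability(recs, bin_edges=[1.0, 2.0])
        se = math.sqrt(p_true * (1 - p_true) / n)
        assert abs(res.prob[0] - p_true) < 3 * se


class TestEstimateLandscape:
    def test_single_level_reduces_to_bin_probability(self, small_config):
        records = sl.generate_population(small_config, seed=1, glucose_levels=[0.003])
        edges = np.linspace(200, 3000, 9)
        grid = sl.estimate_landscape(records, bin_edges=edges)
        row = sl.bin_probability(records, bin_edges=edges)
        assert np.allclose(grid.prob[0], row.prob, equal_nan=True)
        assert np.array_equal(grid.counts[0], row.counts)

    def test_counts_row_sums(self, small_config):
        records = sl.generate_population(small_config, seed=2)
        grid = sl.estimate_landscape(records)
        assert np.all(grid.counts.sum(axis=1) == small_config.n_bags)

    def test_replicate_average_is_pixel_mean(self, small_config):
        edges = np.linspace(200, 3000, 9)
        grids = [
            sl.estimate_landscape(
                sl.generate_population(small_config, seed=s), bin_edges=edges
            )
            for s in (1, 2, 3)
        ]
        avg = sl.average_landscapes(grids)
        stack = np.stack([g.prob for g in grids])
        with np.errstate(invalid="ignore"):
            expected = np.nanmean(stack, axis=0)
        assert np.allclose(avg.prob, expected, equal_nan=True)

    def test_monotone_recovery(self, config):
        """With a generative landscape monotone in both axes, the isotonic
        projection of the estimate changes it by less than sampling noise."""
        cfg = replace(config, n_bags=10_000)
        levels = [0.001, 0.003, 0.01, 0.03]
        records = sl.generate_population(cfg, seed=4, glucose_levels=levels)
        grid = sl.estimate_landscape(records, marker="capacity_true")
        iso = IsotonicRegression(increasing=True)
        for axis, mat in (("rows", grid.prob), ("cols", grid.prob.T)):
            for line in mat:
                ok = ~np.isnan(line)
                if ok.sum() < 3:
                    continue
                x = np.arange(line.size)[ok]
                fitted = iso.fit_transform(x, line[ok])
                rms = np.sqrt(np.mean((fitted - line[ok]) ** 2))
                assert rms < 0.05, f"isotonic violation too large along {axis}"


class TestDoseResponse:
    @staticmethod
    def _logistic(c, floor, ceiling, c50, hill):
        return floor + (ceiling - floor) / (1 + (c50 / c) ** hill)

    def test_exact_recovery_noise_free(self):
        c = np.geomspace(2e-4, 2, 8)
        f = self._logistic(c, 0.1, 0.97, 0.003, 2.0)
        res = sl.fit_dose_response(list(zip(c, f)))
        assert res.c50 == pytest.approx(0.003, rel=1e-6)
        assert res.hill_slope == pytest.approx(2.0, rel=1e-6)
        assert res.floor_frac == pytest.approx(0.1, abs=1e-6)
        assert res.ceiling_frac == pytest.approx(0.97, abs=1e-6)

    def test_midpoint_identity(self):
        c = np.geomspace(1e-4, 1, 8)
        f = self._logistic(c, 0.1, 0.9, 0.003, 3.0)
        res = sl.fit_dose_response(list(zip(c, f)))
        mid = 0.5 * (res.floor_frac + res.ceiling_frac)
        assert res.predict(res.c50) == pytest.approx(mid, abs=1e-9)

    def test_step_location_from_coarse_fractions(self):
        c = np.geomspace(3e-4, 0.03, 5)
        f = self._logistic(c, 0.1, 1.0, 0.003, 2.0)
        res = sl.fit_dose_response(list(zip(c, f)))
        assert res.c50 == pytest.approx(0.003, rel=1e-4)

    def test_flat_fractions_rejected(self):
        with pytest.raises(ValueError, match="no dose-response"):
            sl.fit_dose_response([(c, 0.5) for c in (1e-3, 1e-2, 1e-1, 1.0)])

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            sl.fit_dose_response([(1e-3, 0.1), (1e-2, 0.5), (1e-1, 0.9)])

    def test_c50_bias_vanishes_over_replicates(self, config):
        """ĉ50 is unbiased across seeds: the mean over 100 stochastic fits
        approaches the generative midpoint."""
        cfg = replace(config, n_bags=120)
        estimates = []
        for seed in range(100):
            records = sl.generate_population(cfg, seed=seed)
            res = sl.DoseResponseModel.from_records(records).fit()
            estimates.append(res.c50)
        mean_c50 = np.mean(estimates)
        se = np.std(estimates, ddof=1) / 10
        assert abs(mean_c50 - 0.003) < max(3 * se, 0.0002)

    def test_summary_mentions_c50(self):
        c = np.geomspace(2e-4, 2, 8)
        f = self._logistic(c, 0.1, 1.0, 0.003, 2.0)
        res = sl.fit_dose_response(list(zip(c, f)))
        assert "c50" in res.summary()


class TestMinGlucose:
    def test_saturated_bin_lower_bound(self):
        conc = np.repeat([0.01, 0.1, 1.0], 5)
        res = sl.min_glucose_for_germination(conc, np.ones(15, bool))
        assert res.flag == "lower_bound"
        assert res.concentration_pct == 0.01

    def test_closed_form_inverse(self, rng):
        """Outcomes drawn from a known logistic in log10(c): the fitted 99%
        point matches the analytic inverse."""
        b0, b1 = 1.0, 2.5
        conc = np.repeat(np.geomspace(1e-4, 10.0, 14), 500)
        x = np.log10(conc)
        p = 1 / (1 + np.exp(-(b0 + b1 * x)))
        y = rng.random(conc.size) < p
        res = sl.min_glucose_for_germination(conc, y)
        analytic = 10 ** ((math.log(0.99 / 0.01) - b0) / b1)
        assert res.concentration_pct == pytest.approx(analytic, rel=0.15)

    def test_lower_capacity_bin_needs_more_glucose(self, config):
        """Bags generated with a larger c50 need strictly more glucose."""
        resp = config.landscape
        levels = np.geomspace(1e-4, 1.0, 10)
        rng = np.random.default_rng(8)
        results = {}
        for label, capacity in (("low", 400.0), ("high", 2500.0)):
            conc = np.repeat(levels, 300)
            p = resp.prob(conc, capacity)
            y = rng.random(conc.size) < p
            results[label] = sl.min_glucose_for_germination(conc, y).concentration_pct
        assert results["low"] > results["high"]

    def test_perfect_separation_flagged(self):
        conc = np.repeat([1e-3, 1e-2, 1e-1, 1.0], 4)
        y = conc > 0.05
        res = sl.min_glucose_for_germination(conc, y)
        assert res.flag == "separation"
        assert 1e-2 < res.concentration_pct < 1.0


class TestAssociation:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        res = sl.pearson_association(x, 2 * x + 1)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)

    def test_hand_computed_r(self):
        res = sl.pearson_association([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.pearson_r == pytest.approx(0.6)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            sl.pearson_association([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_generator_hits_target_correlation(self, config):
        """Marker generator: recovered r lies within its sampling CI of the
        configured 0.64 at the study's n = 182."""
        cfg = replace(config, n_bags=182)
        rs = []
        for seed in range(30):
            records = sl.generate_population(cfg, seed=seed, glucose_levels=[2.0])
            res = sl.pearson_association(
                [r.gfp_inducibility for r in records],
                [r.rnap2_level for r in records],
            )
            rs.append(res.pearson_r)
        # Fisher-z SE at n=182 is ~0.075; mean over 30 seeds far tighter
        assert abs(np.mean(rs) - 0.64) < 0.05
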