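"""Depletion-kinetics engine: fitting, derivatives, windows, specific activity."""

import math

import numpy as np
import pytest

from gutnitro import (
    AbioticModelParams,
    AssayTimeSeries,
    BiomassConversion,
    ConsumptionModelParams,
    GrowthModelParams,
    NitriteDepletionKinetics,
    NoiseSpec,
    classify_below_threshold,
    fit_concentration_course,
    initial_linear_window,
    instantaneous_rate,
    rate_vs_biomass,
    simulate_depletion,
    simulate_growth,
    specific_activity,
    summarize_replicates,
)
from gutnitro.kinetics import _spline_fallback


def make_series(t, conc, od=1.0, **kw):
    t = np.asarray(t, dtype=float)
    od = np.full(t.shape, od) if np.isscalar(od) else od
    return AssayTimeSeries(time=t, od600=od, conc=np.asarray(conc, dtype=float), ph=7.0, **kw)


class TestFitConcentrationCourse:
    def test_exact_linear_recovered(self):
        t = np.arange(0.0, 10.1, 1.0)
        fit = fit_concentration_course(make_series(t, 100.0 - 5.0 * t))
        assert fit.name == "linear"
        assert fit.params["slope"] == pytest.approx(5.0, rel=1e-6)

    def test_constant_series_zero_slope(self):
        t = np.arange(0.0, 10.1, 1.0)
        fit = fit_concentration_course(make_series(t, np.full(t.size, 80.0)))
        assert instantaneous_rate(fit, 5.0) == pytest.approx(0.0, abs=1e-9)

    def test_exponential_course_selected(self):
        t = np.arange(0.0, 10.1, 0.5)
        c = 20.0 + 80.0 * np.exp(-0.5 * t)
        fit = fit_concentration_course(make_series(t, c))
        assert fit.name == "exp_offset"
        assert fit.predict(t) == pytest.approx(c, abs=1e-6)

    def test_fitted_course_monotone_non_increasing(self):
        t = np.arange(0.0, 10.1, 0.5)
        rng = np.random.default_rng(0)
        c = np.clip(100 - 12 * t + rng.normal(0, 2, t.size), 0, None)
        fit = fit_concentration_course(make_series(t, c).with_lod(10.0))
        grid = np.linspace(fit.domain[0], fit.domain[1], 100)
        assert np.all(np.diff(fit.predict(grid)) <= 1e-9)

    def test_c0_recovery_monte_carlo(self, no_decay_abiotic):
        # a = 100, km = 20, 2 uM noise: median fitted C(0) within 5% of 100
        t = np.arange(0.0, 4.05, 0.2)
        cons = ConsumptionModelParams(specific_activity=100.0, km=20.0)
        od = np.full(t.shape, 0.25 / 0.36)
        c0s = []
        for seed in range(20):
            exp = simulate_depletion(
                t, od, cons, no_decay_abiotic, 150.0,
                noise=NoiseSpec(conc_sd=2.0, seed=seed), mode="resting",
            )
            fit = fit_concentration_course(exp.series.with_lod(10.0))
            c0s.append(float(fit.predict(0.0)))
        assert abs(np.median(c0s) - 100.0) / 100.0 < 0.05

    def test_all_censored_rejected(self):
        t = np.arange(0.0, 5.0, 1.0)
        s = make_series(t, np.full(t.size, 5.0)).with_lod(10.0)
        with pytest.raises(ValueError):
            fit_concentration_course(s)


class TestInstantaneousRate:
    def test_linear_rate_constant(self):
        t = np.arange(0.0, 10.1, 1.0)
        fit = fit_concentration_course(make_series(t, 100.0 - 5.0 * t))
        assert instantaneous_rate(fit, 3.0) == pytest.approx(5.0, rel=1e-6)
        assert instantaneous_rate(fit, 9.0) == pytest.approx(5.0, rel=1e-6)

    @pytest.mark.parametrize(
        "conc_fn",
        [
            lambda t: 100.0 - 5.0 * t,
            lambda t: 20.0 + 80.0 * np.exp(-0.5 * t),
            lambda t: 100.0 / (1.0 + np.exp(1.2 * (t - 5.0))),
        ],
        ids=["linear", "exp_offset", "logistic"],
    )
    def test_analytic_derivative_matches_finite_differences(self, conc_fn):
        t = np.arange(0.0, 10.1, 0.25)
        fit = fit_concentration_course(make_series(t, conc_fn(t)))
        h = 1e-4
        for tt in [1.0, 3.3, 7.9]:
            fd = -(fit.predict(tt + h) - fit.predict(tt - h)) / (2 * h)
            assert instantaneous_rate(fit, tt) == pytest.approx(fd, rel=1e-6, abs=1e-10)

    def test_spline_derivative_matches_finite_differences(self):
        t = np.arange(0.0, 10.1, 0.5)
        rng = np.random.default_rng(1)
        c = np.clip(100 - 8 * t + rng.normal(0, 1, t.size), 0, None)
        fit = _spline_fallback(t, c)
        h = 1e-4
        # stay away from spline knots: the first derivative is continuous
        # there but the second is not, which degrades central differences
        for tt in [2.26, 5.77]:
            fd = -(fit.predict(tt + h) - fit.predict(tt - h)) / (2 * h)
            assert fit.rate(tt) == pytest.approx(fd, rel=1e-5, abs=1e-8)

    def test_extrapolation_rejected(self):
        t = np.arange(0.0, 10.1, 1.0)
        fit = fit_concentration_course(make_series(t, 100.0 - 5.0 * t))
        with pytest.raises(ValueError):
            instantaneous_rate(fit, 11.0)


class TestRateVsBiomass:
    def test_resting_cells_constant_biomass(self):
        # OD 8 at 0.36 g/L/OD -> X_DW = 2.88 g/L at every timepoint
        t = np.arange(0.0, 2.1, 0.25)
        fit = fit_concentration_course(make_series(t, 100.0 - 30.0 * t, od=8.0))
        x, r, _ = rate_vs_biomass(
            fit, make_series(t, 100.0 - 30.0 * t, od=8.0), BiomassConversion(0.36)
        )
        assert x == pytest.approx(2.88)

    def test_conversion_scaling_halves_activity(self):
        t = np.arange(0.0, 2.1, 0.25)
        s = make_series(t, 100.0 - 30.0 * t, od=8.0)
        fit = fit_concentration_course(s)
        results = []
        for conv in [0.36, 0.72]:
            x, r, _ = rate_vs_biomass(fit, s, BiomassConversion(conv))
            w, _ = initial_linear_window(x, r)
            results.append(specific_activity(x, r, w)[0])
        assert results[0] == pytest.approx(2 * results[1], rel=1e-9)

    def test_censored_tail_excluded(self):
        t = np.arange(0.0, 10.1, 1.0)
        c = np.clip(100.0 - 20.0 * t, 0.0, None)
        s = make_series(t, c, od=1.0).with_lod(10.0)
        fit = fit_concentration_course(s)
        x, r, tt = rate_vs_biomass(fit, s, BiomassConversion(0.36))
        assert tt.max() < 5.0  # first censored point is t = 5 (c = 0)

    def test_growing_culture_biomass_increases(self, fig_growth):
        t = np.arange(0.0, 24.1, 0.5)
        od = simulate_growth(fig_growth, t)
        s = make_series(t, np.linspace(100, 60, t.size), od=od)
        fit = fit_concentration_course(s)
        x, _, _ = rate_vs_biomass(fit, s, BiomassConversion(0.36))
        assert np.all(np.diff(x) >= 0)


class TestInitialLinearWindow:
    def test_perfectly_proportional_uses_all_points(self):
        x = np.arange(1.0, 8.0)
        w, flagged = initial_linear_window(x, 2.0 * x)
        assert (w.start, w.stop) == (0, 7) and not flagged

    def test_saturating_tail_truncated(self):
        # proportional for 5 points, then the substrate runs out
        x = np.arange(1.0, 8.0)
        y = np.array([2.0, 4.0, 6.0, 8.0, 10.0, 6.0, 3.0])
        w, flagged = initial_linear_window(x, y)
        assert (w.start, w.stop) == (0, 5) and not flagged

    def test_min_size_fallback_flagged(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([5.0, 1.0, 9.0])
        w, flagged = initial_linear_window(x, y)
        assert (w.start, w.stop) == (0, 3) and flagged

    def test_all_zero_rates_trivially_linear(self):
        x = np.arange(1.0, 6.0)
        w, flagged = initial_linear_window(x, np.zeros(5))
        assert (w.start, w.stop) == (0, 5) and not flagged


class TestSpecificActivity:
    def test_zero_order_closed_form(self):
        # rate 5 uM/h at X_DW = 0.05 g/L -> 100 umol/gDW/h
        x = np.full(6, 0.05)
        r = np.full(6, 5.0)
        a, se = specific_activity(x, r, slice(0, 6))
        assert a == pytest.approx(100.0)
        assert se == pytest.approx(0.0, abs=1e-9)

    def test_all_zero_rates_zero_activity(self):
        a, _ = specific_activity(np.full(5, 1.0), np.zeros(5), slice(0, 5))
        assert a == 0.0

    def test_window_too_small_rejected(self):
        with pytest.raises(ValueError):
            specific_activity(np.ones(5), np.ones(5), slice(0, 1))


class TestBelowThreshold:
    def test_small_uncertain_activity_flagged(self):
        assert classify_below_threshold(0.3, 0.2, 1.0)

    def test_well_measured_activity_reported(self):
        assert not classify_below_threshold(26.9, 12.2, 1.0)

    def test_boundary_strict(self):
        assert not classify_below_threshold(1.0, 0.0, 1.0)

    def test_replicate_summary(self):
        mean, sd, flag = summarize_replicates([0.2, 0.3, 0.4], threshold=1.0)
        assert mean == pytest.approx(0.3)
        assert flag


class TestEndToEnd:
    def test_resting_cell_recovery_ecoli_scale(self, no_decay_abiotic):
        # truth 10 770 umol/gDW/h; 2 uM noise; median of 20 seeds within 10%
        truth = 10770.0
        t = np.arange(0.0, 2.45, 0.1)
        od = np.full(t.shape, (50.0 / truth) / 0.36)
        cons = ConsumptionModelParams(specific_activity=truth, km=0.0)
        rec = []
        for seed in range(20):
            exp = simulate_depletion(
                t, od, cons, no_decay_abiotic, 150.0,
                noise=NoiseSpec(conc_sd=2.0, seed=seed), mode="resting",
            )
            rec.append(NitriteDepletionKinetics().fit(exp.series).specific_activity_)
        assert abs(np.median(rec) - truth) / truth < 0.10

    def test_unit_invariance_minutes_vs_hours(self):
        t_h = np.arange(0.0, 2.45, 0.1)
        conc = 100.0 - 36.0 * t_h
        s_h = make_series(t_h, conc, od=2.0)
        s_min = make_series(t_h * 60.0, conc, od=2.0)
        a_h = NitriteDepletionKinetics().fit(s_h).specific_activity_
        a_min = NitriteDepletionKinetics().fit(s_min).specific_activity_
        assert a_min * 60.0 == pytest.approx(a_h, rel=1e-6)

    def test_stationary_phase_leak_not_reported_as_activity(self):
        # slow late leak uncorrelated with biomass: classified below threshold
        t = np.arange(0.0, 24.1, 0.5)
        growth = GrowthModelParams(od_initial=0.05, od_max=0.6, mu_max=math.log(2) / 1.1, lag=2.0)
        od = simulate_growth(growth, t)
        base = np.where(t < 12.0, 100.0, 100.0 - 1.0 * (t - 12.0))
        for seed in range(5):
            rng = np.random.default_rng(seed)
            c = np.clip(base + rng.normal(0, 1.0, t.size), 0.0, None)
            est = NitriteDepletionKinetics().fit(make_series(t, c, od=od))
            assert est.below_threshold_

    def test_estimator_sklearn_params_round_trip(self):
        est = NitriteDepletionKinetics(biomass_per_od=0.5)
        assert est.get_params()["biomass_per_od"] == 0.5
        est.set_params(report_threshold=2.0)
        assert est.report_threshold == 2.0
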