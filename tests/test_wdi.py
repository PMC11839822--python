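"""WDI estimators: HLM, regression tolerance limits, PAR, rounding."""

import math

import numpy as np
import pytest
from scipy import stats

import eggwdi as e
from eggwdi.wdi import WdiError, tolerance_factor


def make_fit(n=30, slope=-0.1, intercept=math.log(100.0), s=0.0,
             xbar=15.0, sxx=2000.0, P=0.99, conf=0.95):
    return e.ToleranceLimitFit(n=n, slope=slope, intercept=intercept, s=s,
                               xbar=xbar, sxx=sxx, percentile=P,
                               confidence=conf)


class TestHlm:
    def test_study_half_life_gives_96_days(self):
        est = e.wdi_hlm(228.1)
        assert est.raw_wdi == pytest.approx(95.04, abs=0.01)
        assert est.rounded_wdi == 96

    @pytest.mark.parametrize("t_half,raw,rounded",
                             [(24.0, 10.0, 10), (2.4, 1.0, 1)])
    def test_small_half_lives(self, t_half, raw, rounded):
        est = e.wdi_hlm(t_half)
        assert est.raw_wdi == pytest.approx(raw)
        assert est.rounded_wdi == rounded

    def test_inverse_identity(self):
        for t_half in (1.0, 50.0, 228.1, 1000.0):
            assert e.wdi_hlm(t_half).raw_wdi * 24.0 / 10.0 == pytest.approx(
                t_half)

    def test_nonpositive_half_life_rejected(self):
        with pytest.raises(WdiError):
            e.wdi_hlm(0.0)


class TestRounding:
    @pytest.mark.parametrize("raw,expected",
                             [(80.6, 81), (101.7, 102), (57.0, 57), (0.0, 0),
                              (0.01, 1)])
    def test_ceiling_to_whole_days(self, raw, expected):
        assert e.round_up_wdi(raw) == expected

    def test_negative_rejected(self):
        with pytest.raises(WdiError):
            e.round_up_wdi(-1.0)


class TestResidueLimit:
    def test_ema_substitution_doubles_lloq(self):
        limit = e.ResidueLimit.from_lloq(0.075)
        assert limit.value == pytest.approx(0.15)
        assert limit.basis is e.LimitBasis.TWO_TIMES_LLOQ

    def test_lod_basis(self):
        assert e.ResidueLimit.from_lod(0.03).value == 0.03

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            e.ResidueLimit(0.0)


class TestFitDepletion:
    def test_exact_line_zero_residual(self):
        t = np.arange(10.0)
        pts = list(zip(t, 100.0 * np.exp(-0.1 * t)))
        fit = e.fit_depletion(pts, 0.95, 0.95)
        assert fit.slope == pytest.approx(-0.1, rel=1e-9)
        assert fit.s == pytest.approx(0.0, abs=1e-9)

    def test_two_timepoint_replicates_closed_form(self):
        pts = [(0.0, v) for v in (1.0, 2.0, 4.0, 2.0, 1.0)] + \
              [(10.0, v) for v in (0.5, 1.0, 2.0, 1.0, 0.5)]
        fit = e.fit_depletion(pts, 0.95, 0.95)
        mean0 = np.mean(np.log([1, 2, 4, 2, 1]))
        mean1 = np.mean(np.log([0.5, 1, 2, 1, 0.5]))
        assert fit.slope == pytest.approx((mean1 - mean0) / 10.0)

    def test_singular_design_rejected(self):
        with pytest.raises(WdiError):
            e.fit_depletion([(1.0, 2.0), (1.0, 3.0), (1.0, 4.0)], 0.95, 0.95)

    def test_positive_slope_flagged_not_fatal(self):
        fit = e.fit_depletion([(0, 1.0), (1, 2.0), (2, 4.0)], 0.95, 0.95)
        assert "warning_positive_slope" in fit.diagnostics

    def test_slope_recovered_within_3_se(self):
        """Simulation oracle: OLS slope lands within 3 standard errors of
        truth in >= 99% of replicates."""
        rng = np.random.default_rng(99)
        t = np.repeat(np.arange(20.0, 71.0, 5.0), 10)
        b, a, sig = -0.07, 2.0, 0.3
        hits = 0
        reps = 1000
        sxx = float(np.sum((t - t.mean()) ** 2))
        for _ in range(reps):
            y = a + b * t + sig * rng.normal(size=len(t))
            fit = e.fit_depletion(list(zip(t, np.exp(y))), 0.95, 0.95)
            se = fit.s / math.sqrt(sxx)
            if abs(fit.slope - b) <= 3 * se:
                hits += 1
        assert hits / reps >= 0.99


class TestToleranceLimit:
    def test_zero_variance_limit_is_mean_line(self):
        fit = make_fit(s=0.0)
        t = np.array([0.0, 10.0, 40.0])
        assert np.allclose(e.upper_tolerance_limit(fit, t), fit.predicted(t))

    def test_large_n_factor_approaches_normal_quantile(self):
        fit = make_fit(n=100_000, s=1.0, sxx=1e9, P=0.95, conf=0.95)
        k = tolerance_factor(fit, fit.xbar)
        assert k == pytest.approx(stats.norm.ppf(0.95), rel=0.01)

    def test_factor_matches_pivotal_monte_carlo(self):
        """Coverage-simulation oracle at df = 10, n* = 8."""
        df, neff, P, conf = 10, 8.0, 0.95, 0.95
        zp = stats.norm.ppf(P)
        rng = np.random.default_rng(123)
        N = 200_000
        Z = rng.normal(size=N)
        S = np.sqrt(rng.chisquare(df, N) / df)
        k_mc = np.quantile((zp - Z / math.sqrt(neff)) / S, conf)
        # a fit with df = 10 whose effective n equals neff at a chosen t
        fit = e.ToleranceLimitFit(n=df + 2, slope=-0.1, intercept=0.0, s=1.0,
                                  xbar=0.0, sxx=100.0, percentile=P,
                                  confidence=conf)
        t_at = math.sqrt((1.0 / neff - 1.0 / fit.n) * fit.sxx)
        k = tolerance_factor(fit, t_at)
        assert k == pytest.approx(k_mc, rel=0.02)


class TestWdiFromTolerance:
    def test_zero_variance_crossing_is_analytic(self):
        fit = make_fit(s=0.0)
        est = e.wdi_from_tolerance(fit, e.ResidueLimit(1.0))
        assert est.raw_wdi == pytest.approx(math.log(100.0) / 0.1, abs=0.011)
        assert est.rounded_wdi == 47

    def test_already_compliant_gives_zero(self):
        fit = make_fit(s=0.0)
        est = e.wdi_from_tolerance(fit, e.ResidueLimit(100.0))
        assert est.raw_wdi == 0.0
        assert est.rounded_wdi == 0

    def test_no_crossing_raises_with_window(self):
        fit = make_fit(s=0.0, slope=-1e-5)
        with pytest.raises(WdiError, match="365"):
            e.wdi_from_tolerance(fit, e.ResidueLimit(0.001))

    def test_positive_slope_rejected(self):
        fit = e.ToleranceLimitFit(n=10, slope=0.01, intercept=0.0, s=0.1,
                                  xbar=5.0, sxx=50.0, percentile=0.95,
                                  confidence=0.95)
        with pytest.raises(WdiError):
            e.wdi_from_tolerance(fit, e.ResidueLimit(0.03))

    def test_lower_limit_never_shortens_wdi(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            fit = make_fit(
                n=int(rng.integers(10, 80)),
                slope=-float(rng.uniform(0.02, 0.3)),
                intercept=float(rng.uniform(0.0, 5.0)),
                s=float(rng.uniform(0.0, 0.6)),
                xbar=float(rng.uniform(5, 40)),
                sxx=float(rng.uniform(100, 5000)),
            )
            hi = e.wdi_from_tolerance(fit, e.ResidueLimit(0.15)).raw_wdi
            lo = e.wdi_from_tolerance(fit, e.ResidueLimit(0.03)).raw_wdi
            assert lo >= hi

    def test_higher_percentile_never_shortens_wdi(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            kwargs = dict(
                n=int(rng.integers(10, 80)),
                slope=-float(rng.uniform(0.02, 0.3)),
                intercept=float(rng.uniform(0.0, 5.0)),
                s=float(rng.uniform(0.01, 0.6)),
                xbar=float(rng.uniform(5, 40)),
                sxx=float(rng.uniform(100, 5000)),
            )
            w99 = e.wdi_from_tolerance(make_fit(P=0.99, **kwargs),
                                       e.ResidueLimit(0.03)).raw_wdi
            w95 = e.wdi_from_tolerance(make_fit(P=0.95, **kwargs),
                                       e.ResidueLimit(0.03)).raw_wdi
            assert w99 >= w95


def _augmented_from_lines(times, means, sd, n, rng):
    out = []
    for t, m in zip(times, means):
        vals = np.exp(np.log(m) + sd * rng.standard_normal(n))
        out.append(e.AugmentedTimepoint(float(t), tuple(vals), ()))
    return out


class TestRegulatoryMethods:
    def test_fda_exceeds_ema_core_on_same_window(self):
        rng = np.random.default_rng(3)
        times = np.arange(10.0, 45.0, 5.0)
        means = 3.0 * np.exp(-0.08 * times)
        tps = _augmented_from_lines(times, means, 0.2, 10, rng)
        limit = e.ResidueLimit(0.03)
        pts = [(tp.time, v) for tp in tps for v in tp.values]
        w_fda = e.wdi_from_tolerance(
            e.fit_depletion(pts, 0.99, 0.95), limit).raw_wdi
        w_ema = e.wdi_from_tolerance(
            e.fit_depletion(pts, 0.95, 0.95), limit).raw_wdi
        assert w_fda >= w_ema

    def test_ema_window_restriction_identity_at_7_timepoints(self):
        rng = np.random.default_rng(4)
        times = np.arange(10.0, 45.0, 5.0)  # exactly 7 timepoints
        means = 3.0 * np.exp(-0.08 * times)
        tps = _augmented_from_lines(times, means, 0.2, 10, rng)
        limit = e.ResidueLimit(0.03)
        full = e.wdi_ema(tps, limit)
        pts = [(tp.time, v) for tp in tps for v in tp.values]
        direct = e.wdi_from_tolerance(
            e.fit_depletion(pts, 0.95, 0.95), limit, e.WdiMethod.EMA_MRL)
        assert full.raw_wdi == direct.raw_wdi

    def test_perfectly_linear_data_passes_lack_of_fit(self):
        times = np.arange(10.0, 45.0, 5.0)
        means = 3.0 * np.exp(-0.08 * times)
        # replicate identical values per timepoint: line fits exactly
        tps = [e.AugmentedTimepoint(float(t), (m,) * 10, ())
               for t, m in zip(times, means)]
        est = e.wdi_ema(tps, e.ResidueLimit(0.03))
        assert est.diagnostics["lack_of_fit_p"] == pytest.approx(1.0)

    def test_shallow_tail_window_inverts_ema_above_fda(self):
        """A profile whose final 7 timepoints hover near the limit with a
        shallow slope makes the EMA-window WDI exceed the FDA one, despite
        the FDA method's higher percentile."""
        rng = np.random.default_rng(7)
        steep_t = np.arange(8.0, 36.0, 2.0)
        steep_m = 3.0 * np.exp(-0.1505 * (steep_t - 8.0))
        shallow_t = np.arange(36.0, 64.0, 4.0)[:7]
        shallow_m = steep_m[-1] * np.exp(-0.02 * (shallow_t - 34.0))
        times = np.concatenate([steep_t, shallow_t])
        means = np.concatenate([steep_m, shallow_m])
        tps = _augmented_from_lines(times, means, 0.15, 10, rng)
        limit = e.ResidueLimit(0.03)
        w_fda = e.wdi_fda(tps, limit)
        w_ema = e.wdi_ema(tps, limit)
        assert w_ema.raw_wdi > w_fda.raw_wdi

    def test_ema_needs_three_usable_timepoints(self):
        tps = [e.AugmentedTimepoint(1.0, (1.0,) * 10, ()),
               e.AugmentedTimepoint(2.0, (0.9,) * 10, ())]
        with pytest.raises(WdiError):
            e.wdi_ema(tps, e.ResidueLimit(0.03))


class TestCoverage:
    def test_tolerance_limit_covers_true_percentile_at_nominal_rate(self):
        """1000 simulated datasets from a known log-linear depletion: the
        95/95 UTL must cover the true 95th percentile in 95% +/- 2%."""
        rng = np.random.default_rng(314)
        t = np.repeat(np.arange(10.0), 3)
        a, b, sig = 2.0, -0.1, 0.3
        t0 = 2.0
        true_q = a + b * t0 + stats.norm.ppf(0.95) * sig
        covered = 0
        reps = 1000
        for _ in range(reps):
            y = a + b * t + sig * rng.normal(size=len(t))
            fit = e.fit_depletion(list(zip(t, np.exp(y))), 0.95, 0.95)
            if e.upper_tolerance_limit(fit, t0) >= true_q:
                covered += 1
        assert covered / reps == pytest.approx(0.95, abs=0.02)


class TestPar:
    def test_study_worked_example_600_ppb(self):
        par = e.compute_par(e.ParInputs(adi=5.0, bodyweight=60.0,
                                        partition_fraction=0.20,
                                        consumption=0.1))
        assert par == pytest.approx(600.0)

    def test_identity_scaling(self):
        par = e.compute_par(e.ParInputs(adi=5.0, bodyweight=60.0,
                                        partition_fraction=1.0,
                                        consumption=60.0))
        assert par == pytest.approx(5.0)

    def test_linear_in_adi(self):
        base = e.ParInputs(adi=5.0, bodyweight=60.0, partition_fraction=0.2,
                           consumption=0.1)
        double = e.ParInputs(adi=10.0, bodyweight=60.0,
                             partition_fraction=0.2, consumption=0.1)
        assert e.compute_par(double) == pytest.approx(2 * e.compute_par(base))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            e.ParInputs(adi=5.0, bodyweight=60.0, partition_fraction=1.5,
                        consumption=0.1)
        with pytest.raises(ValueError):
            e.ParInputs(adi=5.0, bodyweight=60.0, partition_fraction=0.2,
                        consumption=0.0)
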