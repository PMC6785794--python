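"""Curve fitting and analytic time-integration for compartment kinetics."""

import numpy as np
import pytest
from scipy import integrate as scipy_integrate

from bmdosim.kinetics import (
    TimeActivityCurve,
    fit_high_curve,
    fit_low_curve,
    integrate_curve,
    to_concentration,
)


def quad_integral(curve, t_split=2000.0):
    """Numerical-quadrature oracle: adaptive quad plus analytic tail."""
    val, _ = scipy_integrate.quad(lambda t: float(curve(t)), 0.0, t_split, limit=400)
    if curve.form == "biexponential":
        tail = (
            curve.a1 / curve.lambda1 * np.exp(-curve.lambda1 * t_split)
            + curve.a2 / curve.lambda2 * np.exp(-curve.lambda2 * t_split)
        )
    else:
        tail = curve.a0_tail / curve.lambda_tail * np.exp(-curve.lambda_tail * t_split)
    return val + tail


class TestFitLowCurve:
    def test_mono_exponential_subset_recovered(self, acquisition_times):
        a = 100.0 * np.exp(-0.01 * acquisition_times)
        curve = fit_low_curve(acquisition_times, a)
        assert curve.a1 == pytest.approx(0.0, abs=1e-6)
        assert curve.a2 == pytest.approx(100.0, rel=1e-8)
        assert curve.lambda2 == pytest.approx(0.01, rel=1e-8)

    def test_biexponential_recovered_from_four_points(self, acquisition_times):
        truth = TimeActivityCurve(
            form="biexponential", a1=80.0, lambda1=0.2, a2=20.0, lambda2=0.005
        )
        curve = fit_low_curve(acquisition_times, truth(acquisition_times))
        assert curve.a1 == pytest.approx(80.0, rel=1e-6)
        assert curve.lambda1 == pytest.approx(0.2, rel=1e-6)
        assert curve.a2 == pytest.approx(20.0, rel=1e-6)
        assert curve.lambda2 == pytest.approx(0.005, rel=1e-6)

    def test_negative_activity_rejected(self, acquisition_times):
        with pytest.raises(ValueError):
            fit_low_curve(acquisition_times, [10.0, -1.0, 5.0, 2.0])

    def test_non_monotone_times_rejected(self):
        with pytest.raises(ValueError):
            fit_low_curve([2.0, 48.0, 24.0, 168.0], [10.0, 5.0, 7.0, 1.0])

    def test_integral_recovery_on_random_draws(self, acquisition_times):
        # the integral a1/l1 + a2/l2 is identifiable even when individual
        # parameters are weakly so
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(200):
            a1, a2 = rng.uniform(1, 100, 2)
            lam1 = rng.uniform(0.05, 0.5)
            lam2 = rng.uniform(0.002, 0.02)
            truth = TimeActivityCurve(
                form="biexponential", a1=a1, lambda1=lam1, a2=a2, lambda2=lam2
            )
            fit = fit_low_curve(acquisition_times, truth(acquisition_times))
            rel = abs(
                integrate_curve(fit).value / (a1 / lam1 + a2 / lam2) - 1.0
            )
            worst = max(worst, rel)
        assert worst < 5e-3


class TestFitHighCurve:
    def test_worked_example(self, acquisition_times):
        curve = fit_high_curve(acquisition_times, [50.0, 72.0, 60.0, 30.0])
        assert curve.slope == pytest.approx(1.0)
        assert curve.lambda_tail == pytest.approx(0.00598, abs=1e-5)
        assert curve.a0_tail == pytest.approx(81.7, abs=0.1)

    def test_single_exponential_is_reproduced_exactly(self, acquisition_times):
        a = 90.0 * np.exp(-0.01 * acquisition_times)
        curve = fit_high_curve(acquisition_times, a)
        assert curve.lambda_tail == pytest.approx(0.01, rel=1e-10)
        # tail holds beyond t2; linear chord holds between the first points
        assert float(curve(100.0)) == pytest.approx(90.0 * np.exp(-1.0), rel=1e-10)

    def test_constant_activities_clamped_with_warning(self, acquisition_times):
        with pytest.warns(UserWarning, match="non-decaying"):
            curve = fit_high_curve(acquisition_times, [40.0] * 4)
        assert curve.slope == 0.0
        assert curve.lambda_tail == pytest.approx(1e-6)

    def test_tail_slope_equals_closed_form_regression(self, acquisition_times):
        rng = np.random.default_rng(7)
        a = rng.uniform(20, 90, 4)
        curve = fit_high_curve(acquisition_times, a)
        t, y = acquisition_times[1:], np.log(a[1:])
        slope = np.sum((t - t.mean()) * (y - y.mean())) / np.sum((t - t.mean()) ** 2)
        assert curve.lambda_tail == pytest.approx(-slope, rel=1e-12)

    def test_back_extrapolation_clamped_at_zero(self):
        # steep rise: the line crosses zero after t = 0
        curve = fit_high_curve([2.0, 24.0, 48.0, 168.0], [1.0, 100.0, 80.0, 40.0])
        assert float(curve(0.0)) == 0.0
        assert float(curve(2.0)) == pytest.approx(1.0)


class TestIntegrateCurve:
    def test_mono_exponential_closed_form(self):
        curve = TimeActivityCurve(
            form="biexponential", a1=0.0, lambda1=0.1, a2=100.0, lambda2=0.1
        )
        assert integrate_curve(curve).value == pytest.approx(1000.0)

    def test_piecewise_worked_example(self, acquisition_times):
        curve = fit_high_curve(acquisition_times, [50.0, 72.0, 60.0, 30.0])
        # 98 (0-2 h) + 1342 (2-24 h) + tail 81.66 e^{-0.00598*24}/0.00598
        assert integrate_curve(curve).value == pytest.approx(1.327e4, rel=1e-3)

    @pytest.mark.parametrize("form", ["biexponential", "piecewise"])
    def test_analytic_matches_quadrature(self, form, acquisition_times):
        rng = np.random.default_rng(11)
        for _ in range(100):
            if form == "biexponential":
                curve = fit_low_curve(
                    acquisition_times,
                    rng.uniform(1, 50) * np.exp(-rng.uniform(0.05, 0.3) * acquisition_times)
                    + rng.uniform(1, 50) * np.exp(-rng.uniform(0.002, 0.02) * acquisition_times),
                )
            else:
                a = np.sort(rng.uniform(10, 100, 4))[::-1]
                a[0] = rng.uniform(5, 120)
                curve = fit_high_curve(acquisition_times, a)
            analytic = integrate_curve(curve).value
            assert analytic == pytest.approx(quad_integral(curve), rel=1e-3)

    def test_linearity_under_scaling(self, acquisition_times):
        curve = fit_high_curve(acquisition_times, [50.0, 72.0, 60.0, 30.0])
        assert integrate_curve(curve.scaled(3.0)).value == pytest.approx(
            3.0 * integrate_curve(curve).value, rel=1e-12
        )


class TestConcentration:
    def test_unit_mass_scaling(self):
        curve = TimeActivityCurve(
            form="biexponential", a1=0.0, lambda1=0.1, a2=6400.0, lambda2=0.1
        )
        conc = to_concentration(curve, 64000.0)
        assert conc.time_integrated() == pytest.approx(1.0)

    def test_concentration_times_mass_is_activity(self, acquisition_times):
        curve = fit_high_curve(acquisition_times, [50.0, 72.0, 60.0, 30.0])
        conc = to_concentration(curve, 1234.5)
        rng = np.random.default_rng(3)
        for t in rng.uniform(0, 300, 10):
            assert float(conc(t)) * 1234.5 == pytest.approx(float(curve(t)), rel=1e-12)

    def test_nonpositive_mass_rejected(self):
        curve = TimeActivityCurve(
            form="biexponential", a1=0.0, lambda1=0.1, a2=1.0, lambda2=0.1
        )
        with pytest.raises(ValueError):
            to_concentration(curve, 0.0)
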