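"""Time-activity curve fitting and analytic time-integrated activities.

Compartment activities quantified at the four acquisition times (2, 24, 48,
168 h) are condensed into analytic curves:

* the **low-uptake compartment** is fitted with a biexponential
  ``a1*exp(-lambda1*t) + a2*exp(-lambda2*t)`` (fast renal excretion plus slow
  whole-body washout), falling back to a mono-exponential when the two rates
  are not identifiable;
* the **high-uptake compartment** uses a linear segment between the first two
  time points (organ uptake is still rising at 2 h) followed by a
  mono-exponential tail fitted by log-linear least squares over the last
  three points.

Both forms integrate in closed form over [0, inf), giving the
time-integrated activities that multiply the S factors in the dose
equations.  No separate physical-decay correction is applied: the fitted
effective rates absorb 177Lu decay, and a rate slower than the physical
decay constant triggers a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

logger = logging.getLogger(__name__)

__all__ = [
    "TimeActivityCurve",
    "TimeIntegratedActivity",
    "ConcentrationCurve",
    "fit_low_curve",
    "fit_high_curve",
    "integrate_curve",
    "to_concentration",
    "LU177_DECAY_CONSTANT_PER_H",
]

#: Physical decay constant of 177Lu (half-life 159.5 h), 1/h.
LU177_DECAY_CONSTANT_PER_H = 0.004345

#: Floor for washout rates in degenerate (non-decaying) fits, 1/h.
LAMBDA_MIN_PER_H = 1e-6


@dataclass
class TimeActivityCurve:
    """Fitted activity-vs-time model for one compartment.

    Two forms are supported.  ``biexponential`` evaluates
    ``a1*exp(-lambda1*t) + a2*exp(-lambda2*t)`` with the convention
    ``lambda1 >= lambda2`` (a mono-exponential is stored with ``a1 = 0``).
    ``piecewise_linear_exponential`` is linear through the first two sample
    points (back-extrapolated to t = 0 and clamped at zero) and an
    exponential ``a0_tail*exp(-lambda_tail*t)`` for ``t >= t2``; the tail
    amplitude is anchored to the log-linear regression over the last three
    points, so its value at ``t2`` is the regression prediction rather than
    the measured activity (any gap against the measurement is logged).
    """

    form: str  # "biexponential" | "piecewise_linear_exponential"
    a1: float = 0.0
    lambda1: float = 1.0
    a2: float = 0.0
    lambda2: float = 1.0
    # piecewise parameters
    t1: float = 0.0
    t2: float = 0.0
    value_t1: float = 0.0
    slope: float = 0.0  # MBq/h on the linear segment
    a0_tail: float = 0.0
    lambda_tail: float = 1.0
    sample_times: np.ndarray | None = None
    sample_activities: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.form not in ("biexponential", "piecewise_linear_exponential"):
            raise ValueError(f"unknown curve form {self.form!r}")
        if self.form == "biexponential":
            if self.a1 < 0 or self.a2 < 0:
                raise ValueError("amplitudes must be >= 0")
            if not (self.lambda1 >= self.lambda2 > 0):
                raise ValueError("need lambda1 >= lambda2 > 0")
        else:
            if self.lambda_tail <= 0:
                raise ValueError("lambda_tail must be > 0")
            if self.t2 <= self.t1:
                raise ValueError("need t2 > t1")

    def __call__(self, t: "np.typing.ArrayLike") -> np.ndarray | float:
        t_arr = np.asarray(t, dtype=float)
        if self.form == "biexponential":
            out = self.a1 * np.exp(-self.lambda1 * t_arr) + self.a2 * np.exp(
                -self.lambda2 * t_arr
            )
        else:
            linear = self.value_t1 + self.slope * (t_arr - self.t1)
            out = np.where(
                t_arr >= self.t2,
                self.a0_tail * np.exp(-self.lambda_tail * t_arr),
                np.maximum(linear, 0.0),
            )
        return out if out.ndim else float(out)

    def scaled(self, k: float) -> "TimeActivityCurve":
        """Curve with all amplitudes multiplied by ``k >= 0``."""
        if k < 0:
            raise ValueError("scale factor must be >= 0")
        if self.form == "biexponential":
            return TimeActivityCurve(
                form=self.form,
                a1=self.a1 * k,
                lambda1=self.lambda1,
                a2=self.a2 * k,
                lambda2=self.lambda2,
            )
        return TimeActivityCurve(
            form=self.form,
            t1=self.t1,
            t2=self.t2,
            value_t1=self.value_t1 * k,
            slope=self.slope * k,
            a0_tail=self.a0_tail * k,
            lambda_tail=self.lambda_tail,
        )


@dataclass(frozen=True)
class TimeIntegratedActivity:
    """Total decays in a compartment, MBq*h over [0, inf)."""

    value: float
    compartment: str = ""

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("time-integrated activity must be >= 0")


@dataclass
class ConcentrationCurve:
    """Activity curve divided by a compartment mass (unit density).

    ``concentration(t) * mass == activity(t)`` for all t; with density
    1 g/cm^3 a value in MBq/g equals MBq/mL, so ``kbq_per_ml`` is just a
    factor-1000 rescale.
    """

    curve: TimeActivityCurve
    mass: float  # g

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("mass must be > 0")

    def __call__(self, t: "np.typing.ArrayLike") -> np.ndarray | float:
        return self.curve(t) / self.mass

    def kbq_per_ml(self, t: "np.typing.ArrayLike") -> np.ndarray | float:
        return self.curve(t) / self.mass * 1000.0

    def time_integrated(self) -> float:
        """Time-integrated concentration, MBq*h/g."""
        return integrate_curve(self.curve).value / self.mass


def _validate_series(times, activities) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    a = np.asarray(activities, dtype=float)
    if t.ndim != 1 or t.shape != a.shape or t.size < 4:
        raise ValueError("need matching 1-D series of >= 4 samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(a <= 0):
        raise ValueError("activities must be > 0")
    return t, a


def _fit_mono(t: np.ndarray, a: np.ndarray) -> tuple[float, float]:
    """Mono-exponential by nonlinear LS, log-linear initialised."""
    slope, intercept = np.polyfit(t, np.log(a), 1)
    lam0 = max(-slope, LAMBDA_MIN_PER_H)
    a0 = float(np.exp(intercept))

    def resid(p):
        return p[0] * np.exp(-p[1] * t) - a

    sol = optimize.least_squares(
        resid,
        x0=[a0, lam0],
        bounds=([0.0, LAMBDA_MIN_PER_H], [np.inf, np.inf]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    return float(sol.x[0]), float(sol.x[1])


def fit_low_curve(times, activities) -> TimeActivityCurve:
    """Biexponential fit for the low-uptake (whole-body remainder) compartment.

    Constrained least squares with non-negative amplitudes and
    ``lambda1 >= lambda2 > 0``.  The slow phase is initialised from a
    log-linear fit of the last two points and the fast phase from the
    early-point residuals.  Falls back to a mono-exponential when the fast
    phase is absent, the solver fails, or the two rates are degenerate
    (relative difference < 1e-3).
    """
    t, a = _validate_series(times, activities)

    lam2_0 = np.log(a[-2] / a[-1]) / (t[-1] - t[-2])
    lam2_0 = max(lam2_0, LAMBDA_MIN_PER_H)
    a2_0 = a[-2] * np.exp(lam2_0 * t[-2])
    resid0 = a - a2_0 * np.exp(-lam2_0 * t)

    fitted: TimeActivityCurve | None = None
    if resid0[0] > 1e-8 * a[0] and resid0[1] > 0 and resid0[0] > resid0[1]:
        lam1_0 = np.log(resid0[0] / resid0[1]) / (t[1] - t[0])
        a1_0 = resid0[0] * np.exp(lam1_0 * t[0])

        def resid(p):
            a1, a2, lam2, dlam = p
            return a1 * np.exp(-(lam2 + dlam) * t) + a2 * np.exp(-lam2 * t) - a

        try:
            sol = optimize.least_squares(
                resid,
                x0=[a1_0, a2_0, lam2_0, max(lam1_0 - lam2_0, LAMBDA_MIN_PER_H)],
                bounds=(
                    [0.0, 0.0, LAMBDA_MIN_PER_H, 0.0],
                    [np.inf, np.inf, np.inf, np.inf],
                ),
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
            )
            a1, a2, lam2, dlam = sol.x
            lam1 = lam2 + dlam
            degenerate = (lam1 - lam2) / lam1 < 1e-3
            if sol.success and not degenerate:
                fitted = TimeActivityCurve(
                    form="biexponential",
                    a1=float(a1),
                    lambda1=float(lam1),
                    a2=float(a2),
                    lambda2=float(lam2),
                    sample_times=t,
                    sample_activities=a,
                )
        except Exception:  # pragma: no cover - solver pathology
            fitted = None

    if fitted is None:
        a0, lam = _fit_mono(t, a)
        fitted = TimeActivityCurve(
            form="biexponential",
            a1=0.0,
            lambda1=lam,
            a2=a0,
            lambda2=lam,
            sample_times=t,
            sample_activities=a,
        )

    if fitted.lambda2 < LU177_DECAY_CONSTANT_PER_H:
        logger.warning(
            "slow washout rate %.3g /h is below the 177Lu physical decay "
            "constant %.3g /h; whole-body clearance cannot be slower than "
            "physical decay",
            fitted.lambda2,
            LU177_DECAY_CONSTANT_PER_H,
        )
    return fitted


def fit_high_curve(times, activities) -> TimeActivityCurve:
    """Linear-then-exponential fit for the high-uptake compartment.

    A straight line joins the first two samples (and is back-extrapolated to
    t = 0, clamped at zero); the washout tail is a log-linear least-squares
    fit over samples 2-4, anchored so the tail at ``t2`` equals the
    regression prediction there.  A non-decaying tail is clamped to a small
    positive rate with a warning.
    """
    t, a = _validate_series(times, activities)
    t1, t2 = float(t[0]), float(t[1])
    slope = (a[1] - a[0]) / (t2 - t1)

    reg_slope, reg_intercept = np.polyfit(t[1:], np.log(a[1:]), 1)
    pred_t2 = float(np.exp(reg_intercept + reg_slope * t2))
    lam_tail = -reg_slope
    if lam_tail < LAMBDA_MIN_PER_H:
        warnings.warn(
            "non-decaying tail in high-uptake fit; clamping rate to "
            f"{LAMBDA_MIN_PER_H} /h",
            stacklevel=2,
        )
        lam_tail = LAMBDA_MIN_PER_H
    a0_tail = pred_t2 * np.exp(lam_tail * t2)

    gap = pred_t2 - a[1]
    if abs(gap) > 1e-9 * max(abs(a[1]), 1.0):
        logger.info(
            "high-curve junction: tail(%g h) = %.6g vs measured %.6g "
            "(gap %.3g); tail anchored to its own regression",
            t2,
            pred_t2,
            a[1],
            gap,
        )

    return TimeActivityCurve(
        form="piecewise_linear_exponential",
        t1=t1,
        t2=t2,
        value_t1=float(a[0]),
        slope=float(slope),
        a0_tail=float(a0_tail),
        lambda_tail=float(lam_tail),
        sample_times=t,
        sample_activities=a,
    )


def integrate_curve(curve: TimeActivityCurve, compartment: str = "") -> TimeIntegratedActivity:
    """Closed-form integral of a fitted curve over [0, inf), MBq*h.

    Biexponential: ``a1/lambda1 + a2/lambda2``.  Piecewise: area of the
    (zero-clamped) linear segment on [0, t2] plus the analytic tail
    ``tail(t2)/lambda_tail``.
    """
    if curve.form == "biexponential":
        if curve.lambda1 <= 0 or curve.lambda2 <= 0:
            raise ValueError("decay rates must be > 0")
        value = curve.a1 / curve.lambda1 + curve.a2 / curve.lambda2
        return TimeIntegratedActivity(value=float(value), compartment=compartment)

    if curve.lambda_tail <= 0:
        raise ValueError("lambda_tail must be > 0")
    # The linear segment is one straight line through (t1, value_t1) with the
    # measured point at t2 at its end; integrate its positive part on [0, t2].
    v0 = curve.value_t1 - curve.slope * curve.t1
    v2 = curve.value_t1 + curve.slope * (curve.t2 - curve.t1)
    if v0 >= 0:
        linear_area = 0.5 * (v0 + v2) * curve.t2
    else:
        # line crosses zero at t_zero; only the triangle after it counts
        t_zero = curve.t1 - curve.value_t1 / curve.slope
        linear_area = 0.5 * v2 * (curve.t2 - t_zero)
    tail_area = curve.a0_tail * np.exp(-curve.lambda_tail * curve.t2) / curve.lambda_tail
    return TimeIntegratedActivity(
        value=float(linear_area + tail_area), compartment=compartment
    )


def to_concentration(curve: TimeActivityCurve, mass: float) -> ConcentrationCurve:
    """Scale an activity curve by 1/mass (g); unit density makes g == mL."""
    return ConcentrationCurve(curve=curve, mass=mass)
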