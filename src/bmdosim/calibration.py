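"""Gamma-camera calibration from a phantom depth series.

A planar source of known activity (a Petri dish of 177Lu) is imaged at a
series of depths in a tissue-equivalent phantom.  The measured count rate
follows ``rate(d) = C0 * exp(-mu_eff * d)``, where ``mu_eff`` is a broad-beam
*effective* linear attenuation coefficient that empirically absorbs scatter
(no explicit scatter correction is applied anywhere in the pipeline) and
``C0 = sensitivity * activity`` is the unattenuated count rate.  Both
parameters are obtained from an ordinary least-squares fit in log space,
which matches the exponential model exactly and is deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["CalibrationModel", "fit_attenuation_sensitivity"]


@dataclass(frozen=True)
class CalibrationModel:
    """Camera sensitivity and effective attenuation for one gamma camera.

    Attributes
    ----------
    sensitivity:
        Count rate per unit activity at zero depth, cps/MBq. Strictly positive.
    mu_eff:
        Effective (broad-beam) linear attenuation coefficient, 1/cm.
        Non-negative.
    fit_residual:
        Root-mean-square residual of the log-linear fit (dimensionless, in
        log-count-rate units). Zero for a noiseless exponential series.
    camera_id:
        Optional identifier; one model is stored per camera.
    """

    sensitivity: float
    mu_eff: float
    fit_residual: float = 0.0
    camera_id: str = ""

    def __post_init__(self) -> None:
        if not self.sensitivity > 0:
            raise ValueError("sensitivity must be > 0")
        if self.mu_eff < 0:
            raise ValueError("mu_eff must be >= 0")

    def predicted_rate(self, activity_mbq: float, depth_cm: float) -> float:
        """Count rate (cps) predicted for ``activity_mbq`` at ``depth_cm``."""
        return self.sensitivity * activity_mbq * float(np.exp(-self.mu_eff * depth_cm))


def fit_attenuation_sensitivity(
    depths: "np.typing.ArrayLike",
    count_rates: "np.typing.ArrayLike",
    true_activity: float,
    camera_id: str = "",
) -> CalibrationModel:
    """Fit sensitivity and effective attenuation from a depth series.

    Parameters
    ----------
    depths:
        Source depths in the phantom, cm. At least two distinct values.
    count_rates:
        Background-subtracted count rates, cps, all strictly positive.
    true_activity:
        Activity of the calibration source, MBq, strictly positive.

    Returns
    -------
    CalibrationModel
        With ``sensitivity = C0 / true_activity`` and ``mu_eff = -slope`` of
        the log-linear fit ``ln(rate) = ln(C0) - mu_eff * d``. A positive
        unconstrained slope (count rate increasing with depth, which is
        unphysical) is clamped to ``mu_eff = 0`` with a warning, refitting
        the intercept as the log-mean rate.
    """
    d = np.asarray(depths, dtype=float)
    r = np.asarray(count_rates, dtype=float)
    if d.shape != r.shape or d.ndim != 1:
        raise ValueError("depths and count_rates must be 1-D arrays of equal length")
    if np.unique(d).size < 2:
        raise ValueError("insufficient depth series: need >= 2 distinct depths")
    if np.any(r <= 0):
        raise ValueError("count rates must be > 0")
    if not true_activity > 0:
        raise ValueError("true_activity must be > 0")

    log_r = np.log(r)
    slope, intercept = np.polyfit(d, log_r, 1)
    if abs(slope) < 1e-12:  # numerically flat series
        slope = 0.0
    if slope > 0:
        warnings.warn(
            "depth series has increasing count rate with depth; "
            "clamping mu_eff to 0",
            stacklevel=2,
        )
        mu_eff = 0.0
        intercept = float(np.mean(log_r))
    else:
        mu_eff = float(-slope)
    c0 = float(np.exp(intercept))
    residual = float(np.sqrt(np.mean((log_r - (intercept - mu_eff * d)) ** 2)))
    model = CalibrationModel(
        sensitivity=c0 / true_activity,
        mu_eff=mu_eff,
        fit_residual=residual,
        camera_id=camera_id,
    )
    logger.debug(
        "calibration fit: sensitivity=%.6g cps/MBq, mu_eff=%.6g /cm, rms=%.3g",
        model.sensitivity,
        model.mu_eff,
        model.fit_residual,
    )
    return model
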