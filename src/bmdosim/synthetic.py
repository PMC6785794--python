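"""Synthetic phantoms, SPECT volumes and cohorts with known ground truth.

Nothing in this module is patient data: it fabricates inputs whose governing
parameters are known exactly, so every pipeline stage can be validated end
to end.

* ``simulate_phantom_planar`` projects a digital two-compartment phantom
  (organ slabs an order of magnitude hotter than the body background) to
  anterior/posterior count images.  Activity in each compartment sits in a
  uniform slab of fixed thickness centred in the body, so the conjugate-view
  formula holds *exactly* and noiseless quantification must recover the
  generating activity to numerical precision.

* ``simulate_spect_volume`` builds a calibrated SPECT volume (kBq/mL) with
  spherical vertebral bodies on an axial gradient peaking around T10-L1,
  optionally with hot metastatic vertebrae.

* ``simulate_cohort`` draws whole patient cohorts: kinetics, body
  habitus, vertebral concentration profiles (lognormal patient effects on
  the axial gradient, a 1.13 male/female lumbar ratio), metastasis status
  with prevalence 24/46, administered activities around 7.5 GBq
  (6.8-8.0 GBq), and a monotone noisy dose -> platelet-nadir response,
  then computes the planar and all four hybrid dose estimates per fraction.

All randomness flows from one seeded generator per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CalibrationModel
from .cohort_stats import CohortRecord
from .dosimetry import (
    DoseInputs,
    DoseResult,
    accumulate_doses,
    bone_marrow_dose_hybrid,
    bone_marrow_dose_planar,
    default_s_factors,
)
from .kinetics import TimeActivityCurve, integrate_curve, to_concentration
from .planar import ACQUISITION_TIMES_H, PlanarStudy
from .spect_voi import (
    LUMBAR_LABELS,
    VERTEBRA_LABELS,
    HybridMethod,
    VertebraMeasurement,
    select_reference_concentration,
)

__all__ = [
    "DEFAULT_VERTEBRAL_MEDIANS",
    "PhantomSpec",
    "CohortSpec",
    "simulate_phantom_planar",
    "simulate_calibration_series",
    "simulate_spect_volume",
    "simulate_cohort",
    "true_dose_table",
]

#: Reference axial concentration profile (kBq/mL): median vertebral
#: activity concentrations of a 177Lu-DOTATATE cohort without skeletal
#: metastases, peaking between T10 and L1 and falling off toward T5 and L5.
DEFAULT_VERTEBRAL_MEDIANS: dict[str, float] = {
    "T5": 14.4,
    "T6": 20.2,
    "T7": 21.3,
    "T8": 25.8,
    "T9": 28.1,
    "T10": 37.1,
    "T11": 47.8,
    "T12": 41.0,
    "L1": 38.4,
    "L2": 35.6,
    "L3": 28.2,
    "L4": 23.9,
    "L5": 24.2,
}

#: Probability that a vertebra is inside the SPECT field of view, matching
#: the visibility counts of a 22-patient reference cohort (T5 in 1 of 22).
VISIBILITY_PROB: dict[str, float] = {
    **{f"T{i}": 0.0 for i in range(1, 5)},
    "T5": 0.05,
    "T6": 0.14,
    "T7": 0.23,
    "T8": 0.41,
    "T9": 0.68,
    "T10": 0.95,
    "T11": 1.0,
    "T12": 1.0,
    "L1": 1.0,
    "L2": 1.0,
    "L3": 1.0,
    "L4": 1.0,
    "L5": 0.95,
}

HYBRID_METHODS = tuple(m.value for m in HybridMethod)


def _ellipse_mask(shape, spacing_cm, center_cm, semi_cm) -> np.ndarray:
    yy, xx = np.meshgrid(
        np.arange(shape[0]) * spacing_cm, np.arange(shape[1]) * spacing_cm, indexing="ij"
    )
    return ((yy - center_cm[0]) / semi_cm[0]) ** 2 + (
        (xx - center_cm[1]) / semi_cm[1]
    ) ** 2 <= 1.0


@dataclass
class PhantomSpec:
    """Digital two-compartment whole-body phantom.

    The body is an ellipse in the coronal plane with constant
    anterior-posterior thickness; activity of both compartments occupies a
    slab of ``source_thickness_cm`` centred in that thickness (the geometry
    under which conjugate-view quantification is exact).  The high-uptake
    compartment is a set of elliptical "organs"; the low-uptake compartment
    is the rest of the body.  Kinetics: biexponential washout for the low
    compartment, linear uptake to 24 h then exponential washout for the
    high compartment (both exactly of the fitted model families).
    """

    injected_activity_mbq: float = 7500.0
    body_length_cm: float = 170.0
    body_width_cm: float = 44.0
    body_thickness_cm: float = 20.0
    source_thickness_cm: float = 8.0
    mu_eff_per_cm: float = 0.11
    pixel_spacing_cm: float = 0.5
    sensitivity_cps_per_mbq: float = 10.0
    # 10 cm/min whole-body scan under a 40-cm detector: each pixel row is in
    # view for ~4 min
    scan_duration_per_pixel_s: float = 240.0
    body_weight_g: float = 75000.0
    # low-compartment biexponential (fractions of injected activity)
    low_a1_frac: float = 0.55
    low_lambda1: float = 0.15
    low_a2_frac: float = 0.18
    low_lambda2: float = 0.022
    # high-compartment piecewise curve (fractions of injected activity)
    high_frac_2h: float = 0.14
    high_frac_24h: float = 0.18
    high_lambda_tail: float = 0.008
    #: true marrow-to-low-compartment concentration ratio at the L4 level
    true_marrow_ratio: float = 3.4
    # organ layout: (center_y, center_x, semi_y, semi_x) in cm
    organs: tuple[tuple[float, float, float, float], ...] = (
        (52.0, 27.0, 9.0, 7.5),   # liver
        (50.0, 12.0, 5.0, 3.5),   # spleen
        (64.0, 15.0, 4.5, 2.5),   # left kidney
        (64.0, 29.0, 4.5, 2.5),   # right kidney
    )

    def __post_init__(self) -> None:
        if self.injected_activity_mbq < 0:
            raise ValueError("injected activity must be >= 0")
        if not 0 < self.source_thickness_cm <= self.body_thickness_cm:
            raise ValueError("need 0 < source thickness <= body thickness")
        if self.low_a1_frac + self.low_a2_frac + self.high_frac_2h > 1.0 + 1e-9:
            raise ValueError("compartment fractions exceed injected activity")

    @property
    def image_shape(self) -> tuple[int, int]:
        ny = int(np.ceil(self.body_length_cm / self.pixel_spacing_cm)) + 8
        nx = int(np.ceil(self.body_width_cm / self.pixel_spacing_cm)) + 8
        return ny, nx

    def body_mask(self) -> np.ndarray:
        cy = self.image_shape[0] * self.pixel_spacing_cm / 2
        cx = self.image_shape[1] * self.pixel_spacing_cm / 2
        return _ellipse_mask(
            self.image_shape,
            self.pixel_spacing_cm,
            (cy, cx),
            (self.body_length_cm / 2, self.body_width_cm / 2),
        )

    def high_mask(self) -> np.ndarray:
        mask = np.zeros(self.image_shape, dtype=bool)
        for cy, cx, sy, sx in self.organs:
            mask |= _ellipse_mask(
                self.image_shape, self.pixel_spacing_cm, (cy, cx), (sy, sx)
            )
        return mask & self.body_mask()

    def high_area_cm2(self) -> float:
        return float(self.high_mask().sum()) * self.pixel_spacing_cm**2

    def true_low_curve(self) -> TimeActivityCurve:
        return TimeActivityCurve(
            form="biexponential",
            a1=self.low_a1_frac * self.injected_activity_mbq,
            lambda1=self.low_lambda1,
            a2=self.low_a2_frac * self.injected_activity_mbq,
            lambda2=self.low_lambda2,
        )

    def true_high_curve(self) -> TimeActivityCurve:
        a_2h = self.high_frac_2h * self.injected_activity_mbq
        a_24h = self.high_frac_24h * self.injected_activity_mbq
        t1, t2 = ACQUISITION_TIMES_H[0], ACQUISITION_TIMES_H[1]
        return TimeActivityCurve(
            form="piecewise_linear_exponential",
            t1=t1,
            t2=t2,
            value_t1=a_2h,
            slope=(a_24h - a_2h) / (t2 - t1),
            a0_tail=a_24h * np.exp(self.high_lambda_tail * t2),
            lambda_tail=self.high_lambda_tail,
        )

    def low_mass_g(self) -> float:
        return self.body_weight_g - self.high_area_cm2() * self.body_thickness_cm

    def true_vertebral_concentrations(self) -> dict[str, float]:
        """Axial profile scaled so L4 sits at ``true_marrow_ratio`` times the
        low-compartment concentration at 24 h (kBq/mL)."""
        low_curve = self.true_low_curve()
        c_low_24 = float(low_curve(24.0)) / self.low_mass_g() * 1000.0
        scale = self.true_marrow_ratio * c_low_24 / DEFAULT_VERTEBRAL_MEDIANS["L4"]
        return {k: v * scale for k, v in DEFAULT_VERTEBRAL_MEDIANS.items()}


def _slab_projection_factor(mu: float, body_t: float, source_t: float) -> float:
    """Mean attenuation of a uniform centred slab source, one view.

    Integral of exp(-mu z) over the slab divided by its thickness, with z
    the depth below the entry surface: ``exp(-mu (d - t)/2) (1 - e^{-mu t})
    / (mu t)``.  Equals 1 when mu = 0.
    """
    if mu == 0:
        return 1.0
    return float(
        np.exp(-mu * (body_t - source_t) / 2.0)
        * (1.0 - np.exp(-mu * source_t))
        / (mu * source_t)
    )


def simulate_phantom_planar(
    spec: PhantomSpec,
    time_h: float,
    noise: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[PlanarStudy, dict[str, float]]:
    """Project the phantom to an anterior/posterior pair at one time point.

    Returns the study plus the ground-truth compartment activities (MBq).
    The posterior image is returned as seen from behind (mirrored), as a
    camera would record it.
    """
    if noise and rng is None:
        raise ValueError("noise requires a seeded rng")
    body = spec.body_mask()
    high = spec.high_mask()
    low = body & ~high

    a_high = float(spec.true_high_curve()(time_h))
    a_low = float(spec.true_low_curve()(time_h))

    act_map = np.zeros(spec.image_shape, dtype=float)  # MBq per pixel column
    if high.sum():
        act_map[high] = a_high / high.sum()
    if low.sum():
        act_map[low] = a_low / low.sum()

    atten = _slab_projection_factor(
        spec.mu_eff_per_cm, spec.body_thickness_cm, spec.source_thickness_cm
    )
    rate = spec.sensitivity_cps_per_mbq * act_map * atten  # cps per pixel
    counts_ant = rate * spec.scan_duration_per_pixel_s
    counts_post = counts_ant.copy()  # symmetric slab: identical by geometry
    if noise:
        counts_ant = rng.poisson(counts_ant).astype(float)
        counts_post = rng.poisson(counts_post).astype(float)

    study = PlanarStudy(
        anterior=counts_ant,
        posterior=counts_post[:, ::-1],  # as viewed from behind
        time_post_injection=time_h,
        pixel_area=spec.pixel_spacing_cm**2,
        scan_duration_per_pixel=spec.scan_duration_per_pixel_s,
        camera_id="synthetic",
    )
    return study, {"a_high": a_high, "a_low": a_low}


def simulate_calibration_series(
    spec: PhantomSpec,
    depths_cm: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0, 16.0),
    activity_mbq: float = 100.0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Noiseless depth series consistent with the phantom's camera model."""
    d = np.asarray(depths_cm, dtype=float)
    rates = (
        spec.sensitivity_cps_per_mbq
        * activity_mbq
        * np.exp(-spec.mu_eff_per_cm * d)
    )
    return d, rates, activity_mbq


def simulate_spect_volume(
    vertebra_concs: dict[str, float],
    metastases: tuple[str, ...] = (),
    background: float = 10.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    spacing_mm: tuple[float, float, float] = (3.0, 3.0, 3.0),
    vertebra_radius_mm: float = 12.0,
    vertebra_pitch_mm: float = 32.0,
    metastasis_factor: float = 3.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Calibrated SPECT volume (kBq/mL) with spherical vertebral bodies.

    Vertebrae are stacked along the first (axial) array axis at
    ``vertebra_pitch_mm`` intervals; metastatic labels are multiplied by
    ``metastasis_factor``.  Returns the volume and a ground-truth table
    (label, centre in mm, concentration, metastasis flag).
    """
    for label in vertebra_concs:
        if label not in VERTEBRA_LABELS:
            raise ValueError(f"unknown vertebra label {label!r}")
    if any(c < 0 for c in vertebra_concs.values()):
        raise ValueError("concentrations must be >= 0")
    if vertebra_pitch_mm < 2 * vertebra_radius_mm:
        raise ValueError("overlapping vertebra placements")

    labels = [lab for lab in VERTEBRA_LABELS if lab in vertebra_concs]
    n = len(labels)
    margin = vertebra_radius_mm + 2 * max(spacing_mm)
    extent_z = n * vertebra_pitch_mm + 2 * margin
    extent_xy = 2 * margin + 2 * vertebra_radius_mm
    shape = (
        int(np.ceil(extent_z / spacing_mm[0])),
        int(np.ceil(extent_xy / spacing_mm[1])),
        int(np.ceil(extent_xy / spacing_mm[2])),
    )
    vol = np.full(shape, float(background))

    coords = [np.arange(shape[ax]) * spacing_mm[ax] for ax in range(3)]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    cy = (shape[1] - 1) * spacing_mm[1] / 2
    cx = (shape[2] - 1) * spacing_mm[2] / 2

    rows = []
    for i, label in enumerate(labels):
        cz = margin + (i + 0.5) * vertebra_pitch_mm
        conc = vertebra_concs[label]
        met = label in metastases
        if met:
            conc *= metastasis_factor
        inside = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= vertebra_radius_mm**2
        vol[inside] = conc
        rows.append(
            {
                "label": label,
                "z_mm": cz,
                "y_mm": cy,
                "x_mm": cx,
                "concentration_kbq_ml": conc,
                "metastasis": met,
            }
        )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vol = np.maximum(vol + rng.normal(0.0, noise_sd, size=vol.shape), 0.0)
    return vol, pd.DataFrame(rows)


@dataclass
class CohortSpec:
    """Statistical description of a synthetic treatment cohort.

    Defaults follow the study conditions being emulated: 46 patients,
    skeletal-metastasis prevalence 24/46, administered activity
    7.5 GBq per fraction (6.8-8.0), two fractions, a male/female lumbar
    concentration ratio of 1.13, and a vertebral axial profile shaped like
    ``DEFAULT_VERTEBRAL_MEDIANS``.
    """

    n_patients: int = 46
    male_fraction: float = 24 / 46
    metastasis_prevalence: float = 24 / 46
    male_l1l4_ratio: float = 1.13
    #: multiplies metastatic vertebral concentrations (hybrid dose elevation)
    metastasis_elevation: float = 1.6
    #: number of metastatic vertebrae per affected patient (inclusive range)
    metastatic_vertebra_range: tuple[int, int] = (1, 4)
    #: lognormal sigma of the per-patient scaling of the axial profile
    patient_profile_sigma: float = 0.25
    #: per-vertebra multiplicative measurement noise (lognormal sigma)
    vertebra_noise_sigma: float = 0.15
    #: cycle-to-cycle lognormal jitter on patient kinetic parameters
    kinetic_jitter_sigma: float = 0.05
    #: geometric mean of the true marrow-to-low-compartment ratio (L4 level)
    marrow_ratio_gm: float = 3.4
    marrow_ratio_sigma: float = 0.3
    #: platelet-nadir drop per Gy of true cumulative marrow dose
    toxicity_slope_per_gy: float = 0.45
    toxicity_noise_sd: float = 0.10
    admin_activity_mean_gbq: float = 7.5
    admin_activity_range_gbq: tuple[float, float] = (6.8, 8.0)
    n_fractions: int = 2
    seed: int = 0
    #: freeze all patient-level heterogeneity (habitus, kinetics, visibility)
    #: so that dose varies only through the administered activity; used for
    #: strictly monotone zero-noise constructions
    deterministic_patients: bool = False

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("need n_patients >= 1")
        for p in (self.male_fraction, self.metastasis_prevalence):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if self.n_fractions < 1:
            raise ValueError("need n_fractions >= 1")

    @classmethod
    def monotone_zero_noise(cls, **overrides) -> "CohortSpec":
        """Spec with every noise source off and identical patients.

        Doses then scale strictly with administered activity, so the
        dose -> platelet-nadir relation is exactly monotone and Spearman
        correlations are -1 by construction.
        """
        defaults = dict(
            metastasis_prevalence=0.0,
            male_fraction=0.0,
            patient_profile_sigma=0.0,
            vertebra_noise_sigma=0.0,
            marrow_ratio_sigma=0.0,
            kinetic_jitter_sigma=0.0,
            toxicity_noise_sd=0.0,
            deterministic_patients=True,
        )
        defaults.update(overrides)
        return cls(**defaults)


def _draw_patient_kinetic_params(rng: np.random.Generator) -> dict[str, float]:
    """Patient-level kinetic parameters (stable physiology across fractions)."""
    return {
        "a1_frac": rng.uniform(0.50, 0.65),
        "lam1": rng.uniform(0.10, 0.25),
        "a2_frac": rng.uniform(0.13, 0.24),
        "lam2": rng.uniform(0.015, 0.030),
        "h2": rng.uniform(0.10, 0.18),
        "h_rise": rng.uniform(1.05, 1.35),
        "lam_tail": rng.uniform(0.006, 0.010),
    }


def _fraction_kinetics(
    params: dict[str, float],
    rng: np.random.Generator,
    admin_mbq: float,
    jitter_sigma: float,
):
    """Curves for one fraction: patient parameters with small cycle-to-cycle
    lognormal jitter (intra-patient kinetics are highly reproducible)."""
    j = lambda: float(rng.lognormal(0.0, jitter_sigma)) if jitter_sigma else 1.0
    a1 = params["a1_frac"] * j() * admin_mbq
    lam1 = params["lam1"] * j()
    a2 = params["a2_frac"] * j() * admin_mbq
    lam2 = params["lam2"] * j()
    low = TimeActivityCurve(
        form="biexponential", a1=a1, lambda1=max(lam1, lam2), a2=a2, lambda2=lam2
    )
    h2 = params["h2"] * j() * admin_mbq
    h24 = h2 * params["h_rise"]
    lam_tail = params["lam_tail"] * j()
    t1, t2 = ACQUISITION_TIMES_H[0], ACQUISITION_TIMES_H[1]
    high = TimeActivityCurve(
        form="piecewise_linear_exponential",
        t1=t1,
        t2=t2,
        value_t1=h2,
        slope=(h24 - h2) / (t2 - t1),
        a0_tail=h24 * np.exp(lam_tail * t2),
        lambda_tail=lam_tail,
    )
    return low, high


def simulate_cohort(spec: CohortSpec) -> tuple[list[CohortRecord], pd.DataFrame]:
    """Draw a full cohort and compute every method's dose per fraction.

    Returns the cohort records (feeding :func:`dose_response_analysis`) and
    a tidy ground-truth table with the generating parameters and true doses.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.admin_activity_range_gbq
    records: list[CohortRecord] = []
    truth_rows: list[dict] = []

    for i in range(spec.n_patients):
        pid = f"SYN{i + 1:03d}"
        det = spec.deterministic_patients
        male = (not det) and rng.random() < spec.male_fraction
        sex = "male" if male else "female"
        if det:
            weight, abdominal_thickness, high_area, baseline = 71000.0, 21.0, 280.0, 260.0
        else:
            weight = float(
                np.clip(rng.normal(80000 if male else 67000, 8000), 48000, 120000)
            )
            abdominal_thickness = float(
                np.clip(rng.normal(22 if male else 20, 2.0), 16, 30)
            )
            high_area = float(np.clip(rng.normal(280, 40), 150, 450))
            baseline = float(np.clip(rng.normal(260, 70), 128, 520))
        m_high = high_area * abdominal_thickness
        m_low = weight - m_high
        mets = rng.random() < spec.metastasis_prevalence
        s_set = default_s_factors(sex)

        # patient-level vertebral profile; the male/female lumbar ratio is a
        # ratio of *concentrations*, so the marrow-ratio sex factor must undo
        # the lower male low-compartment concentration (heavier habitus)
        patient_scale = float(rng.lognormal(0.0, spec.patient_profile_sigma))
        exp_mlow_male = 80000.0 - 280.0 * 22.0
        exp_mlow_female = 67000.0 - 280.0 * 20.0
        sex_factor = (
            spec.male_l1l4_ratio * exp_mlow_male / exp_mlow_female if male else 1.0
        )
        marrow_ratio = float(
            rng.lognormal(np.log(spec.marrow_ratio_gm), spec.marrow_ratio_sigma)
        )
        if det:
            visible = {lab: lab in DEFAULT_VERTEBRAL_MEDIANS for lab in VERTEBRA_LABELS}
        else:
            visible = {
                lab: (rng.random() < VISIBILITY_PROB[lab]) for lab in VERTEBRA_LABELS
            }
        met_labels: tuple[str, ...] = ()
        if mets:
            lo_n, hi_n = spec.metastatic_vertebra_range
            n_met = int(rng.integers(lo_n, hi_n + 1))
            candidates = [lab for lab in VERTEBRA_LABELS if visible[lab]]
            met_labels = tuple(
                str(lab)
                for lab in rng.choice(
                    candidates, size=min(n_met, len(candidates)), replace=False
                )
            )

        per_method_fraction: dict[tuple[str, int], DoseResult] = {}
        nadirs: dict[int, float] = {}
        cumulative_true = 0.0
        per_method_results: dict[str, list[DoseResult]] = {
            m: [] for m in ("planar",) + HYBRID_METHODS
        }
        l1l4_mean = None
        if det:
            kin_params = {
                "a1_frac": 0.575,
                "lam1": 0.175,
                "a2_frac": 0.185,
                "lam2": 0.0225,
                "h2": 0.14,
                "h_rise": 1.2,
                "lam_tail": 0.008,
            }
        else:
            kin_params = _draw_patient_kinetic_params(rng)

        for fraction in range(1, spec.n_fractions + 1):
            admin_gbq = float(np.clip(rng.normal(spec.admin_activity_mean_gbq, 0.3), lo, hi))
            admin_mbq = admin_gbq * 1000.0
            low_curve, high_curve = _fraction_kinetics(
                kin_params, rng, admin_mbq, spec.kinetic_jitter_sigma
            )
            a_tilde_low = integrate_curve(low_curve, "low").value
            a_tilde_high = integrate_curve(high_curve, "high").value
            conc_curve = to_concentration(low_curve, m_low)
            c_tilde_low = conc_curve.time_integrated()
            c_low_24 = float(conc_curve.kbq_per_ml(24.0))

            # vertebral concentrations for this fraction's SPECT
            base_l4 = marrow_ratio * c_low_24
            profile_scale = base_l4 / DEFAULT_VERTEBRAL_MEDIANS["L4"]
            measurements = []
            for lab in VERTEBRA_LABELS:
                if lab not in DEFAULT_VERTEBRAL_MEDIANS or not visible[lab]:
                    continue
                conc = (
                    DEFAULT_VERTEBRAL_MEDIANS[lab]
                    * profile_scale
                    * patient_scale
                    * sex_factor
                    * float(rng.lognormal(0.0, spec.vertebra_noise_sigma))
                )
                if lab in met_labels:
                    conc *= spec.metastasis_elevation
                measurements.append(
                    VertebraMeasurement(
                        label=lab,
                        concentration=conc,
                        metastasis=lab in met_labels,
                        visible=True,
                    )
                )
            if fraction == 1:
                lumbar = [
                    m.concentration
                    for m in measurements
                    if m.label in LUMBAR_LABELS[:4]
                ]
                l1l4_mean = float(np.mean(lumbar)) if lumbar else None

            inputs = DoseInputs(
                c_tilde_low=c_tilde_low,
                a_tilde_low=a_tilde_low,
                a_tilde_high=a_tilde_high,
                s=s_set,
                administered_activity_gbq=admin_gbq,
            )
            results = {"planar": bone_marrow_dose_planar(inputs, fraction=fraction)}
            for method in HYBRID_METHODS:
                try:
                    c_ref = select_reference_concentration(measurements, method)
                except ValueError:
                    continue
                k = c_ref / c_low_24
                results[method] = bone_marrow_dose_hybrid(
                    inputs, k, method=method, fraction=fraction
                )

            # true dose: the actual marrow concentration ratio, with the
            # metastatic elevation feeding the marrow of affected patients
            k_true = marrow_ratio * patient_scale * sex_factor
            if met_labels:
                k_true *= 1.0 + 0.15 * len(met_labels)
            true_dose = bone_marrow_dose_hybrid(
                inputs, k_true, method="V_SPECT", fraction=fraction
            ).dose_gy
            cumulative_true += true_dose

            ratio = (
                1.0
                - spec.toxicity_slope_per_gy * cumulative_true
                + (rng.normal(0.0, spec.toxicity_noise_sd) if spec.toxicity_noise_sd else 0.0)
            )
            ratio = float(np.clip(ratio, 0.05, 1.5))
            nadirs[fraction] = ratio * baseline

            for method, res in results.items():
                per_method_results[method].append(res)
                cum = accumulate_doses(per_method_results[method])
                per_method_fraction[(method, fraction)] = cum

            truth_rows.append(
                {
                    "patient_id": pid,
                    "fraction": fraction,
                    "sex": sex,
                    "skeletal_metastases": mets,
                    "administered_gbq": admin_gbq,
                    "a_tilde_low_mbq_h": a_tilde_low,
                    "a_tilde_high_mbq_h": a_tilde_high,
                    "c_tilde_low_mbq_h_g": c_tilde_low,
                    "k_true": k_true,
                    "true_dose_gy": true_dose,
                    "true_cumulative_gy": cumulative_true,
                    "relative_nadir": ratio,
                    **{
                        f"dose_{m}_gy": results[m].dose_gy
                        for m in results
                    },
                }
            )

        records.append(
            CohortRecord(
                patient_id=pid,
                sex=sex,
                skeletal_metastases=mets,
                baseline_platelets=baseline,
                nadir_platelets=nadirs,
                doses=per_method_fraction,
                l1_l4_mean_concentration=l1l4_mean,
            )
        )

    return records, pd.DataFrame(truth_rows)


def true_dose_table(records: list[CohortRecord]) -> pd.DataFrame:
    """Tidy per-patient, per-fraction, per-method dose table."""
    rows = []
    for rec in records:
        for (method, fraction), res in sorted(rec.doses.items()):
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "fraction": fraction,
                    "method": method,
                    "dose_gy": res.dose_gy,
                    "dose_gy_per_7p4gbq": res.dose_gy_per_7p4gbq,
                    "cumulative_gy": res.cumulative_gy,
                }
            )
    return pd.DataFrame(rows)
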