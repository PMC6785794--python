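"""Ground-truth fidelity and determinism of the synthetic generators."""

import numpy as np
import pandas as pd
import pytest

from bmdosim.calibration import fit_attenuation_sensitivity
from bmdosim.planar import conjugate_view_activity, mirror_posterior
from bmdosim.spect_voi import sphere_voi_mask, voi_concentration
from bmdosim.synthetic import (
    DEFAULT_VERTEBRAL_MEDIANS,
    CohortSpec,
    PhantomSpec,
    simulate_calibration_series,
    simulate_cohort,
    simulate_phantom_planar,
    simulate_spect_volume,
)


def quantify_with_true_masks(spec, study, calib):
    """Compartment activities using the phantom's generating masks."""
    post = mirror_posterior(study.posterior)
    out = {}
    for name, mask in (("high", spec.high_mask()), ("low", spec.body_mask() & ~spec.high_mask())):
        out[name] = conjugate_view_activity(
            float(study.anterior[mask].sum()),
            float(post[mask].sum()),
            study.scan_duration_per_pixel,
            calib,
            spec.body_thickness_cm,
            spec.source_thickness_cm,
        )
    return out


class TestPhantomPlanar:
    def test_noiseless_conjugate_view_recovery(self, small_phantom):
        d, r, act = simulate_calibration_series(small_phantom)
        calib = fit_attenuation_sensitivity(d, r, act)
        study, truth = simulate_phantom_planar(small_phantom, 24.0)
        acts = quantify_with_true_masks(small_phantom, study, calib)
        assert acts["low"] == pytest.approx(truth["a_low"], rel=1e-6)
        assert acts["high"] == pytest.approx(truth["a_high"], rel=1e-6)

    def test_same_seed_is_bit_identical(self, small_phantom):
        s1, _ = simulate_phantom_planar(
            small_phantom, 24.0, noise=True, rng=np.random.default_rng(11)
        )
        s2, _ = simulate_phantom_planar(
            small_phantom, 24.0, noise=True, rng=np.random.default_rng(11)
        )
        np.testing.assert_array_equal(s1.anterior, s2.anterior)
        np.testing.assert_array_equal(s1.posterior, s2.posterior)

    def test_zero_injected_activity_gives_blank_images(self):
        spec = PhantomSpec(injected_activity_mbq=0.0, pixel_spacing_cm=1.0)
        study, truth = simulate_phantom_planar(spec, 24.0)
        assert study.anterior.sum() == 0.0
        assert truth["a_low"] == 0.0

    def test_no_excretion_spec_conserves_activity_at_2h(self):
        # slow phases at the physical decay rate only; 2-h total ~ injected
        spec = PhantomSpec(
            low_a1_frac=0.0,
            low_a2_frac=0.85,
            low_lambda2=0.004345,
            high_frac_2h=0.15,
            high_frac_24h=0.15,
            high_lambda_tail=0.004345,
            pixel_spacing_cm=1.0,
        )
        _, truth = simulate_phantom_planar(spec, 2.0)
        total = truth["a_low"] + truth["a_high"]
        assert total == pytest.approx(spec.injected_activity_mbq, rel=0.05)

    def test_high_compartment_is_order_of_magnitude_hotter(self, small_phantom):
        study, _ = simulate_phantom_planar(small_phantom, 24.0)
        high = small_phantom.high_mask()
        low = small_phantom.body_mask() & ~high
        ratio = study.anterior[high].mean() / study.anterior[low].mean()
        assert ratio > 8.0

    def test_noise_requires_rng(self, small_phantom):
        with pytest.raises(ValueError, match="rng"):
            simulate_phantom_planar(small_phantom, 24.0, noise=True)


class TestSpectVolume:
    def test_noiseless_vertebra_reads_back_exactly(self):
        vol, table = simulate_spect_volume({"T10": 37.1, "L4": 23.9}, background=10.0)
        row = table[table.label == "T10"].iloc[0]
        mask = sphere_voi_mask(
            vol.shape, (3.0, 3.0, 3.0), (row.z_mm, row.y_mm, row.x_mm)
        )
        assert voi_concentration(vol, mask) == pytest.approx(37.1, abs=1e-9)

    def test_metastasis_scaled_and_flagged(self):
        _, table = simulate_spect_volume(
            {"T7": 21.3, "L4": 23.9}, metastases=("T7",), metastasis_factor=3.0
        )
        t7 = table[table.label == "T7"].iloc[0]
        assert t7.concentration_kbq_ml == pytest.approx(3 * 21.3)
        assert bool(t7.metastasis)

    def test_same_seed_identical_volume(self):
        v1, _ = simulate_spect_volume(DEFAULT_VERTEBRAL_MEDIANS, noise_sd=2.0, seed=4)
        v2, _ = simulate_spect_volume(DEFAULT_VERTEBRAL_MEDIANS, noise_sd=2.0, seed=4)
        np.testing.assert_array_equal(v1, v2)

    def test_overlapping_placement_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            simulate_spect_volume({"L4": 20.0}, vertebra_pitch_mm=10.0,
                                  vertebra_radius_mm=12.0)


class TestCohort:
    def test_same_seed_byte_identical_tables(self):
        _, t1 = simulate_cohort(CohortSpec(n_patients=10, seed=21))
        _, t2 = simulate_cohort(CohortSpec(n_patients=10, seed=21))
        pd.testing.assert_frame_equal(t1, t2)

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_patients=0)

    def test_metastasis_elevates_hybrid_doses(self):
        records, truth = simulate_cohort(CohortSpec(n_patients=200, seed=8))
        f1 = truth[truth.fraction == 1]
        with_m = f1[f1.skeletal_metastases]["dose_V_SPECT_gy"]
        without = f1[~f1.skeletal_metastases]["dose_V_SPECT_gy"]
        assert with_m.mean() > without.mean()

    def test_null_metastasis_elevation_is_exchangeable(self):
        # with elevation factor 1 and no extra marrow burden the dose
        # distributions with/without metastases coincide in mean
        spec = CohortSpec(n_patients=400, seed=12, metastasis_elevation=1.0)
        _, truth = simulate_cohort(spec)
        f1 = truth[truth.fraction == 1]
        with_m = f1[f1.skeletal_metastases]["dose_planar_gy"]
        without = f1[~f1.skeletal_metastases]["dose_planar_gy"]
        assert abs(with_m.mean() / without.mean() - 1.0) < 0.1

    def test_male_lumbar_concentration_ratio(self):
        spec = CohortSpec(n_patients=600, seed=3, patient_profile_sigma=0.0,
                          vertebra_noise_sigma=0.0, marrow_ratio_sigma=0.0)
        records, _ = simulate_cohort(spec)
        male = np.mean([r.l1_l4_mean_concentration for r in records if r.sex == "male"])
        female = np.mean([r.l1_l4_mean_concentration for r in records if r.sex == "female"])
        assert male / female == pytest.approx(1.13, rel=0.1)

    def test_stronger_toxicity_slope_strengthens_correlation(self):
        from bmdosim.cohort_stats import dose_response_analysis

        medians = []
        for slope in (0.15, 0.45):
            rs = []
            for seed in range(1, 7):
                spec = CohortSpec(seed=seed, toxicity_slope_per_gy=slope)
                records, _ = simulate_cohort(spec)
                rs.append(dose_response_analysis(records, "V_SPECT", 2, "all").r_s)
            medians.append(np.median(rs))
        assert medians[1] < medians[0]
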