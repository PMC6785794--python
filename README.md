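# bmdosim

Image-based **bone-marrow dosimetry for ¹⁷⁷Lu-DOTATATE therapy**, with the
cohort statistics that relate absorbed dose to platelet toxicity.

Peptide receptor radionuclide therapy of neuroendocrine tumours delivers
¹⁷⁷Lu-DOTATATE in fractions of ~7.4 GBq. The bone marrow is a dose-limiting
organ, but its activity cannot be measured directly: it is dispersed, mixed
with fat, and sometimes infiltrated by skeletal metastases. `bmdosim`
implements two families of image-based estimates for medical physicists and
dosimetry researchers:

* **Planar two-compartment method.** Whole-body conjugate-view scintigraphy
  at 2, 24, 48 and 168 h is segmented into a high-uptake compartment
  (liver, spleen, kidneys, tumours) and a low-uptake compartment (the rest
  of the body). The marrow dose is

  D_BM = C̃_BM · φ_BM←BM · Δ · 1.8 + Ã_low · S_BM←low + Ã_high · S_BM←high

  where C̃_BM is the time-integrated activity concentration of the
  low-uptake compartment (MBq·h/g), Δ = 147 keV is the electron energy
  released per ¹⁷⁷Lu decay, φ = 1 the self-absorption fraction, 1.8 a fixed
  population marrow-to-remainder concentration ratio, and the S factors are
  mass-weighted photon cross-dose factors per compartment.

* **Hybrid planar/SPECT methods (L4-, V-, L-, T-SPECT).** The fixed ratio
  1.8 is replaced by a patient-specific ratio k measured from 0.7-cm³
  spherical VOIs centred in vertebral bodies on a calibrated SPECT/CT at
  24 h: L4-SPECT uses the L4 vertebra (falling back L5 → L3 → L2 when
  metastatic), V-/L-/T-SPECT use the median concentration over all visible,
  lumbar, or thoracic vertebrae.

Supporting pieces: γ-camera calibration from a phantom depth series
(sensitivity and effective attenuation µ_eff), biexponential and
linear+exponential time–activity fits with closed-form time integrals,
Spearman/Wilcoxon dose–response statistics with exact small-sample p
values, and a synthetic-data module that generates phantom projections,
SPECT volumes and whole cohorts with known ground truth — every pipeline
stage is testable end to end without patient data.

## Worked example

```python
import numpy as np
from bmdosim import (
    PhantomSpec, CohortSpec, simulate_cohort, dose_response_analysis,
)
from bmdosim.pipeline import run_phantom_pipeline

# full image chain on a digital phantom: calibrate, project, segment,
# quantify, fit, dose
result = run_phantom_pipeline(PhantomSpec())
for method, res in result["doses"].items():
    print(f"{method:9s} {res.dose_gy_per_7p4gbq:.3f} Gy/7.4 GBq")

# a 46-patient synthetic cohort and its dose-response statistics
records, truth = simulate_cohort(CohortSpec(seed=1))
r = dose_response_analysis(records, "V_SPECT", fraction=2, group="all")
print(f"V-SPECT fraction 2: r_s = {r.r_s:.2f}, p = {r.p_value:.2g}")
```

prints

```
planar    0.200 Gy/7.4 GBq
L4_SPECT  0.374 Gy/7.4 GBq
V_SPECT   0.439 Gy/7.4 GBq
L_SPECT   0.440 Gy/7.4 GBq
T_SPECT   0.421 Gy/7.4 GBq
V-SPECT fraction 2: r_s = -0.89, p = 9.3e-17
```

The planar estimate is lowest (its fixed ratio 1.8 understates the true
marrow concentration of this phantom, whose vertebral ratio is 3.4); the
four hybrid variants differ through their choice of reference vertebrae.
In the cohort, the cumulative dose after fraction 2 correlates negatively
with the relative platelet nadir — higher marrow dose, deeper platelet drop.

A command-line interface mirrors the library
(`bmdosim calibrate | simulate | segment | quantify | kinetics | dose |
cohort | run-all`); `bmdosim run-all --config run.toml` executes the whole
chain into an output directory with a content-hashed run manifest.

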