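# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `bmdosim`. It states what the code computes and under
which conditions the tests validate it; it does not report empirical
results beyond what the test suite and `scripts/acceptance.py` themselves
compute.

## Camera calibration

A planar ¹⁷⁷Lu source of known activity imaged at depths *d* in a
tissue-equivalent phantom follows `rate(d) = S·A·exp(−µ_eff·d)`. Both
parameters come from ordinary least squares on `ln rate` vs `d` — the model
is exactly log-linear, the fit is deterministic, and on a noiseless
exponential series it is exact. µ_eff is *effective* (broad beam): no
scatter correction is applied anywhere, so scatter is absorbed empirically
into the coefficient. A positive fitted slope (count rate growing with
depth) is unphysical and is clamped to µ_eff = 0 with a warning. One
`CalibrationModel` is stored per camera identifier; mapping cameras to
studies is left to configuration, since a site may operate several models
of camera with different sensitivities.

Defaults used by the synthetic camera: sensitivity 10 cps/MBq, µ_eff
0.11 cm⁻¹ — typical for a medium-energy collimator at the 208-keV ¹⁷⁷Lu
photopeak with a ±10% window.

## Planar two-compartment quantification

The two views are combined pixelwise as √(anterior × mirrored posterior);
the posterior image is flipped about the vertical axis first, because the
two detectors face each other. Segmentation:

1. the *whole body* is the largest connected component of the
   Gaussian-smoothed geometric mean above `wb_threshold_frac` of its
   maximum, morphologically closed and hole-filled (the closing is done on
   a padded copy so bodies touching the image frame are not eroded);
2. within the body, the *high-uptake* compartment is every pixel of the
   **unfiltered** geometric mean at or above `split_threshold_frac` of the
   within-body maximum; the *low-uptake* compartment is the rest. The two
   masks partition the body exactly.

The split fraction defaults to 0.35 of the within-body maximum — a value
chosen on synthetic phantoms where the organ-to-background projection
contrast is ≥ 3.5 at all four time points; it is a configuration parameter
and should be tuned per site on real data. The body threshold defaults to
0.002: it must sit *below* background/maximum contrast at the late 168-h
time point (where organs dominate the remaining activity by two orders of
magnitude) and low enough that smoothing-attenuated border pixels are kept;
pixels outside the body carry no counts, so an over-inclusive body mask is
harmless for quantification.

Compartment activity uses the conjugate-view formula

A = √(R_A·R_P)/S · exp(µd/2) · (µt/2)/sinh(µt/2),

with body thickness *d* measured over the abdomen (one scalar per patient,
applied to both compartments) and source-slab thickness *t* = 8 cm, a
general organ thickness. The self-attenuation factor is evaluated by series
for µt/2 < 10⁻⁴. For a uniform slab source centred in the body the formula
is exact, which is the geometry the synthetic phantom realises. Counts are
used as acquired (no decay correction to injection time); the kinetic fits
absorb physical decay into effective rates.

Compartment masses assume unit density: m_high = (projected high area) ×
(abdominal thickness), m_low = body weight − m_high.

## Kinetics

* **Low-uptake compartment**: `a₁e^(−λ₁t) + a₂e^(−λ₂t)` with a₁,a₂ ≥ 0 and
  λ₁ ≥ λ₂ > 0, fitted by bounded least squares on the four samples.
  Initialisation: slow phase from the log-linear fit of the last two
  points, fast phase from the early-point residuals. The fit falls back to
  a mono-exponential when no fast component is present, the solver fails,
  or the rates collapse (relative difference < 10⁻³). A fitted λ₂ below the
  ¹⁷⁷Lu physical decay constant (0.004345 h⁻¹) is logged as a warning —
  whole-body clearance cannot be slower than physical decay. With four
  points and four parameters the noiseless fit is exact; the *integral*
  a₁/λ₁ + a₂/λ₂ is well identified even when the individual parameters are
  not.
* **High-uptake compartment**: a straight line through the 2-h and 24-h
  samples (uptake still rising), then a mono-exponential tail from a
  log-linear least-squares fit over samples 2–4 — all three points, not a
  two-point solve, to use the available data. The tail is anchored to its
  own regression prediction at t₂, so its value there can differ slightly
  from the measured 24-h activity; the gap is logged. Before 2 h the line
  is back-extrapolated to t = 0 and clamped at zero. A non-decaying tail is
  clamped to λ = 10⁻⁶ h⁻¹ with a warning.

Time-integrated activities are closed-form: `a₁/λ₁ + a₂/λ₂` for the
biexponential; area of the clamped linear segment on [0, t₂] plus
`tail(t₂)/λ` for the piecewise form. Integration starts at t = 0 with the
fitted forms extended there. Concentrations divide by compartment mass at
unit density, making MBq/g and MBq/mL interchangeable.

## Dose equations and S factors

Self-dose conversion: 1 MBq·h/g of time-integrated concentration with
Δ = 147 keV per decay deposits 3.6×10⁹ × 147 × 1.602177×10⁻¹⁶ J/g =
0.08478 Gy. The planar equation multiplies the low-compartment concentration
by the fixed ratio 1.8; the hybrid equation replaces 1.8 with
k = c_vert(24 h)/c_low(24 h), the vertebral SPECT concentration over the
*fitted* low-compartment concentration curve evaluated at 24 h (the fitted
curve, rather than the raw 24-h planar sample, for noise robustness; the
raw alternative is one line of configuration). At k = 1.8 the two equations
are arithmetically identical.

Cross-dose S factors are mass-weighted means over the organs of each
compartment, Σ(m_o/Σm)·S_o. The shipped sex-keyed table
(`data/s_factors.toml`) contains stated approximations of order 10⁻⁹–10⁻⁸
Gy/(MBq·h) assembled from photon specific-absorbed-fraction estimates at
reference adult organ masses; each dose result records the table version.
Only photon cross-dose and electron self-dose are modelled, matching the
equation structure. Cross terms contribute ≲ 1% of a typical marrow dose,
so the approximation in the table has little leverage; sites can supply
their own table.

Doses are reported absolute and normalised to 7.4 GBq administered
activity (linear rescaling). Cumulative dose across fractions is a plain
sum, guarded against mixing methods or duplicate fraction indices.

## Vertebral VOIs and reference selection

Spheres of 0.7 cm³ (radius 5.51 mm) are rendered on the voxel lattice by
voxel-centre membership — no partial-volume weighting, since the sphere is
deliberately smaller than the vertebral body; the discretised volume
converges to the nominal volume as the grid is refined. Selection rules:
L4-SPECT walks L4 → L5 → L3 → L2 skipping metastatic or invisible
vertebrae (an exhausted chain is an error); V-/L-/T-SPECT take the median
over all visible / lumbar / thoracic vertebrae, *including* metastatic
ones — the median itself is the robustness mechanism. Any visible thoracic
vertebra participates in T-SPECT (T1–T4 are simply rarely in the field of
view). Vertebra centres come from a CSV (human- or generator-produced);
automatic vertebra detection is out of scope, as is image registration —
SPECT is assumed resampled to the CT grid.

## Statistics

The hematologic endpoint is the relative platelet nadir (nadir/baseline),
so a toxic dose effect appears as a *negative* Spearman correlation.
Fraction-1 analyses pair fraction-1 dose with the fraction-1 nadir window;
later fractions use the cumulative dose. Spearman r_s is the Pearson
correlation of mid-ranks; p values are exact permutation probabilities
(full enumeration) for n ≤ 9 and the t-approximation above. The Wilcoxon
rank-sum test enumerates all group assignments exactly for pooled n ≤ 12
and uses the tie-corrected normal approximation above. Groups with fewer
than three complete pairs return a flagged NA result that never counts as
significant. No multiple-testing adjustment is applied; each test is
reported with its raw p value at α = 0.05.

## Synthetic data: what it emulates, and what it does not

The generator defines the study conditions under which the pipeline is
validated.

**Phantom** (`PhantomSpec`): an elliptical body outline of constant
20-cm anterior–posterior thickness; both compartments occupy 8-cm slabs
centred in depth, which is exactly the geometry under which the
conjugate-view formula holds — so noiseless quantification must recover
the generating activities to numerical precision, and any failure is a
pipeline defect. Organ ellipses (liver, spleen, two kidneys, ~330 cm²)
form the high-uptake compartment, roughly an order of magnitude hotter
than background in projection. Kinetics are drawn exactly from the fitted
model families (biexponential low compartment, linear-then-exponential
high compartment), so curve fitting introduces no model error in the round
trip. Projection uses the closed-form slab attenuation per pixel column;
Poisson noise is optional and seeded. Scan timing (10 cm/min under a 40-cm
detector ⇒ ~240 s effective dwell) gives realistic count levels of order
10²–10³ per body pixel.

**SPECT volumes**: spherical vertebral bodies (12-mm radius, 32-mm pitch)
on a uniform background, with the axial concentration profile shaped like
the reference medians peaking between T10 and L1; metastatic vertebrae are
multiplied by a hot factor and flagged. Gaussian voxel noise is optional.

**Cohorts** (`CohortSpec`): 46 patients by default, male fraction 24/46,
skeletal-metastasis prevalence 24/46, administered activity ~7.5 GBq per
fraction (clipped to 6.8–8.0), two fractions. Kinetic parameters are drawn
per *patient* with small (σ = 0.05 lognormal) cycle-to-cycle jitter —
intra-patient kinetics are highly reproducible, and this is what makes
cumulative-dose correlations strengthen after fraction 2 for every method.
Vertebral profiles are the reference axial medians scaled per patient
(lognormal σ = 0.25) and anchored so that the L4-to-low-compartment
concentration ratio has geometric mean 3.4 (σ = 0.3) — roughly twice the
planar method's fixed 1.8, reflecting that the fixed ratio understates
marrow concentration. The male/female lumbar concentration ratio of 1.13
is imposed on *concentrations*; because heavier male habitus lowers the
low-compartment concentration, the male marrow-ratio factor compensates by
the expected male/female low-compartment mass ratio. Platelet response is
`clamp(1 − 0.45/Gy × true cumulative dose + N(0, 0.1), 0.05, 1.5)`, a
monotone noisy dose–toxicity model whose "true" dose uses the patient's
actual marrow ratio, with metastatic marrow burden adding 15% per affected
vertebra. A `monotone_zero_noise` constructor freezes all heterogeneity and
noise so that dose varies only through administered activity; Spearman
correlations are then −1 by construction, which the round-trip tests
exploit.

Not emulated: anthropomorphic anatomy, camera point-spread functions,
septal penetration, SPECT reconstruction artefacts, partial-volume effects
at vertebral boundaries, marrow fat-fraction physiology, platelet-count
dynamics beyond a single nadir per fraction. Passing tests therefore
demonstrate correctness of the *computational chain* under its stated
assumptions, not clinical accuracy on patient images.

## Problem sizes and numerical tolerances

The test suite and acceptance script use the default phantom
(0.5-cm pixels, ~350×100 images), 100 Poisson replicates for noisy
recovery, 200 random curves for the quadrature cross-check (tolerance
0.1%), exhaustive enumeration for rank tests up to n = 8 (two-sample) and
n = 9 (paired ranks), and a 20-seed bank of 46-patient cohorts for the
fraction-comparison property. Solver tolerances for curve fitting are set
to 10⁻¹⁵ (xtol/ftol/gtol); rate floors are 10⁻⁶ h⁻¹. These sizes run the
whole suite in well under a minute on one CPU.

## Known limitations

* The split threshold (0.35) is a placeholder calibrated on synthetic
  contrast; real planar images with scatter tails and overlapping organs
  will need site-specific tuning.
* The S-factor table is an approximation with ~1% dose leverage; exact
  specific-absorbed-fraction compilations should replace it for clinical
  use.
* The piecewise high-uptake curve is discontinuous at 24 h by the gap
  between the measured activity and the tail regression (logged); the
  integral follows the measured chord up to 24 h and the regression tail
  after.
* One body thickness per patient is applied to both compartments; regional
  thickness variation is ignored.
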