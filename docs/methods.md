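# Methods

`tcplan` implements a voxel-level, probabilistic treatment-planning study
for prostate IMRT: patient-specific clonogen maps drive a
tumour-control-probability (TCP) objective that is robust to geometric
uncertainty, and the resulting margin-less plans are compared with
conventional margin-based uniform-dose plans at matched expected tumour
control. This note records the models, the numerical choices, and what
the synthetic data do and do not show.

## The TCP model

Tumour control is the Poisson probability that no clonogenic cell
survives. For voxel *i* with clonogen density ρ_i (cells/mm³), voxel
volume V_i (mm³) and per-fraction dose d_i (Gy) in n fractions:

    TCP_i = exp[ −ρ_i V_i exp( −α n d_i − α n d_i² / (α/β)
                               + ln(2) T_exp / T_pot ) ]

Linear-quadratic cell kill with α/β = 3.1 Gy; clonogen repopulation over
the treatment time T_exp = 1.4 n days (daily weekday fractions) with
potential doubling time T_pot = 42 days. Accelerated repopulation is
excluded — only the constant repopulation term is present. Voxels are
independent, so the target TCP is the product over CTV voxels, computed
in the log domain. Population heterogeneity in radiosensitivity is a
log-normal α with arithmetic mean 0.15 Gy⁻¹ and SD 0.04 Gy⁻¹, discretised
at p = 11 equiprobable quantile midpoints with uniform weights. Whether
the stated moments belong to α or to ln α is ambiguous in the
radiobiology literature; both parameterisations are supported
(`moments_of_log`), with arithmetic moments of α as the default. The
defaults follow the high-risk prostate fit of Wang et al. (2003), and the
absolute TCP values should be read comparatively, not as clinical
probabilities.

Numerical guards: survivor counts are capped at 700 in the Poisson
exponent (beyond which TCP is numerically zero); all products are
accumulated as sums of log-survivors; the expectation sums use a
max-shifted log-sum-exp so the optimiser's `−ln⟨TCP⟩` objective stays
finite even when ⟨TCP⟩ underflows.

## Geometric uncertainty and the expectation machinery

Geometric errors are per-axis (AP, LR, SI) Gaussians with a systematic
component (mean M, SD Σ — a treatment-long offset) and a random component
(SD σ — per-fraction fluctuation). The shipped preset combines prostate
delineation and intrafraction-motion uncertainties:

| axis | M (mm) | Σ (mm) | σ (mm) | margin (mm) |
|------|--------|--------|--------|-------------|
| AP   | −0.4   | 2.56   | 1.26   | 7.3         |
| LR   |  0.2   | 2.47   | 0.67   | 6.6         |
| SI   |  0.1   | 2.58   | 1.18   | 7.3         |

For uniform planning these feed the van Herk recipe
(margin = 2.5 Σ + 0.7 σ, rounded to 0.1 mm for reporting only) and an
anisotropic ellipsoidal CTV→PTV dilation. For probabilistic planning:

* **Random errors blur the dose.** Separable Gaussian kernels with SD
  σ/spacing voxels, truncated at 3 SD and renormalised; zero padding
  (dose outside the computation box is zero). The kernel is symmetric, so
  the blur is self-adjoint — the gradient chain relies on this.
* **Systematic errors translate the patient.** The expectation over
  shifts is a tensor-product quadrature of N(M, Σ²) per axis. Sampling
  the blurred dose at shifted voxel positions uses trilinear
  interpolation (zero outside the box — conservative: clonogens carried
  off-grid receive no dose). The sign convention: a patient displaced by
  t means tissue planned at x receives the dose at x + t.

Two quadrature rules are provided. Gauss–Hermite (default, 5 nodes/axis,
125 shifts) is cheap and exact for smooth integrands, which is what the
optimiser needs; its accuracy on trilinearly interpolated fields plateaus
near 1e−3 absolute in ⟨TCP⟩ because the integrand has voxel-scale kinks.
The `grid` rule (uniformly spaced nodes over ±5 Σ weighted by the
Gaussian density) converges ~h² even for kinked integrands and is used
when high-accuracy expectation values are needed (the Monte-Carlo
cross-checks use 33 nodes/axis). Both plans are always evaluated with the
same rule, so comparative results do not depend on this choice.

## Clonogen maps

From a tumour-probability map and an areal cell-density map (cells/mm²),
both defined on the planning grid:

1. areal → volumetric density by the 3/2 power (uniform density across
   the slice assumed);
2. ROC threshold on the probability map: the threshold in
   {0, 0.01, …, 1} maximising sensitivity + specificity against the
   ground-truth tumour mask, computed over CTV voxels, positives called
   at ≥ t, ties broken toward the smallest optimal threshold (the most
   sensitive optimum, deterministic);
3. binary prediction × volumetric density × CTV mask;
4. one global cohort scale factor bringing the median total cell count to
   10⁷ (the literature clonogen estimate for high-risk prostate cancer).
   The lower median is used for even cohorts (configurable; the reference
   cohort is odd-sized so the choice is moot).

Resampling of intensive maps between grids is block averaging for
integer factors (mass-conserving) with a linear-interpolation fallback;
upsampling is out of scope.

## Dose engine

A deliberately simple beamlet engine replaces a clinical pencil-beam
system; it is photon-physics-inspired and **not clinically validated**.
Water-equivalent geometry; per beamlet, dose = depth term × lateral term:
a linear build-up ramp (15 mm) times exponential attenuation
(μ = 0.005/mm), and a Gaussian penumbra (SD 3 mm) about the divergent ray
from a 1000 mm source-axis distance; unit-normalised at the
isocentre-plane depth on the beamlet axis. Entries below 1e−4 of each
column's maximum are dropped; beamlets that miss the target are culled.
The beamlet grid covers the target plus a 10 mm margin in the beam's-eye
view. Depth is the upstream path length through the external contour,
ray-marched at 1 mm. The planning contribution under study is the
objective, not the kernel: any positive linear dose operator exercises
it, and all tests that need dose physics use closed-form oracles on
analytic phantoms.

Default beam arrangement: seven coplanar 6 MV-style fields at gantry
0°, 40°, 80°, 110°, 250°, 280°, 310°, beamlet width 2.5 mm.

## Plan optimisation

Both optimisers run projected quasi-Newton (L-BFGS-B, non-negative
beamlet weights) with analytic gradients through the sparse influence
adjoint; stopping at relative objective change below the configured
tolerance or 500 iterations. Replays are bit-deterministic for a fixed
config.

**Plan A (uniform).** Piecewise-quadratic objectives on total dose:
square deviation (PTV, 78 Gy), square underdose (CTV, 78.8 Gy — pulling
the cold tail above the prescription so CTV V78 ≥ 99% is reachable),
rank-based dose-volume penalties for the OARs (rectum V50 ≤ 50%,
V60 ≤ 25%; bladder V65 ≤ 50%; femoral heads V50 ≤ 5%), an overdose
shave on the femoral heads, and a square-overdose term on the body shell
to suppress hotspots. The DV penalty charges only the lowest-ranked
voxels above the reference dose beyond the allowed volume fraction
(highest doses are spared), matching the convention of matRad-style
planning systems. Clinical DV limits are reported post hoc, never
silently enforced; an infeasible plan is returned with failure flags.
Penalty weights are configuration; the shipped defaults were calibrated
once so that all DV limits pass on the default phantom, and are recorded
in the default config.

**Plan B (biological).** Margin-less. Objective: −ln⟨TCP⟩ (same optimum
as −⟨TCP⟩, far better conditioned) plus the same OAR penalty forms
evaluated on the *expected* dose (systematic-shift-weighted blurred
dose), including a soft square-underdose coverage term on expected CTV
dose at the prescription (the ⟨V78⟩ ≥ 99% requirement is reported, not
hard-constrained). The gradient chains the voxel-TCP derivative through
the product, the shift weights, the sampling adjoint, the blur (its own
adjoint) and the influence adjoint; it matches central finite differences
to 1e−4 relative in the tests. Optimisation starts from uniform fluence
delivering half the prescription to the CTV: the log-domain objective is
stable at low ⟨TCP⟩, and a sub-prescription start lets the optimiser
shape dose upward where clonogens are rather than downward everywhere
else. A caveat found during development: with no OAR terms at all the
optimum saturates (⟨TCP⟩ → 1) and the dose *shape* beyond saturation is
no longer determined — degenerate-case tests therefore include a
symmetric soft cap to keep the optimum interior.

**Isoeffect scaling.** ⟨TCP⟩ is strictly increasing in a global dose
scale (monotonicity is a tested invariant), so bisection on s ∈ [0.05, 5]
brings any plan to ⟨TCP⟩ = 0.95 within 1e−4. Blur and shift sampling are
linear in dose, so the sampled dose matrix is computed once and rescaled
inside the loop. The optimal fluence profile is assumed invariant under
scaling (the same simplification the comparison framework rests on).

## Synthetic patients

Real inputs of this kind — registered, histology-validated
tumour-probability and cell-density maps — are not publicly available, so
the study runs on seeded synthetic patients:

* 48 × 48 × 24 grid at 2 × 2 × 2.5 mm (the planning resolution of the
  motivating datasets; ~10 mm³ voxels);
* simple solids: ellipsoidal prostate CTV (~16 cm³) centred in a body
  ellipsoid, posterior rectum tube, anterior–superior bladder ellipsoid,
  two lateral femoral-head spheres. One shared anatomy across the cohort
  (mirroring single-surrogate-CT planning studies); organ specifications
  that overlap the CTV or escape the body are rejected;
* one to three ellipsoidal lesions per patient with centres inside the
  CTV; cohort lesion-size multipliers are geometrically spaced so total
  cell counts span more than an order of magnitude, as in real high-risk
  cohorts;
* probability map = 0.1 baseline + 0.75 × Gaussian-smoothed (3 mm) lesion
  indicator + correlated noise (Gaussian-filtered white noise, 6 mm
  correlation length, SD 0.12), clipped to [0, 1];
* areal density = 150 cells/mm² background + 250 cells/mm² lesion
  elevation + correlated noise (SD 40), clipped at zero. With the
  3/2-power conversion these levels give unscaled cohort totals of
  1e7–1e9 cells, the order of magnitude of published prostatectomy
  cohorts. No noise model for real prediction maps is available, so the
  levels are configuration, not calibration.

Everything is bit-deterministic in (config, seed); cohort seeds derive
from one master seed.

What passing tests on these phantoms show: the pipeline's algebra and
the direction of the planning effect (OAR sparing at matched tumour
control). What they do not show: performance on real prediction maps,
whose spatial statistics (registration artefacts, prediction-model
correlations, histology-driven lesion shapes) are not emulated, nor
absolute dosimetric accuracy, which would require a validated dose
engine.

## Study sizes and runtimes

The default study — 5 patients, 48 × 48 × 24 grid, 7 beams (~3 700
beamlets, 11 M influence entries), 125 systematic shifts × 11 α samples —
was chosen to keep a full cohort run in the ten-minute range on one CPU
while preserving every structural feature of the method. All numerical
tolerances above (quadrature rules and node counts, survivor cap,
bisection tolerance, optimiser stopping) are stated where they are
introduced.

## Known limitations

* The dose engine is a toy: no heterogeneity, scatter, leaf sequencing or
  deliverability.
* No NTCP model; OAR burden is summarised by expected gEUD (a = 6 for
  rectum and bladder), DV metrics and mean doses.
* No rotations or organ deformation; rectum and bladder shapes are
  invariant and share the prostate's motion.
* No hypoxia, no spatially varying radiosensitivity, no time-varying
  clonogen density, no urethral sparing.
* Femoral-head mean dose may increase under biological optimisation in
  these phantoms (lateral beams carry the boost); the rectum/bladder
  sparing result does not depend on it.
* "Integral dose" is reported in Gy·cm³; only relative changes are
  meaningful.
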