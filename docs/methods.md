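# Methods

This note documents the models, conventions and numerical choices behind
petvalid, and what its synthetic validation does and does not demonstrate
about real scanner data.

## Fill accounting and decay

All ground truth derives from radionuclide-calibrator assays.  A fill is
recorded as a pre-injection and residual (post-injection) assay; net
activity at any reference time is obtained by decay-correcting both assays
independently with A(t) = A₀·2^(−Δt/T½) and differencing, which makes the
result independent of any intermediate common correction time (tested to
1e-10 relative).  Half-lives are registry data: F-18 109.771 min, Ga-68
67.71 min, Cu-64 12.7 h, Zr-89 3.25 d, I-124 4.2 d.  Concentrations are
always referenced to the acquisition start of the image being analyzed
("concentration at scan time").

Volume-by-weight uses a default water density of 0.9982 g/mL (20 °C),
overridable.  Timestamps are timezone-aware; each assay carries a
device-clock offset to the scanner clock, flagged by QC at ≥ 60 s.

Fill QC encodes the recommended operating ranges as configurable defaults:
3–7 kBq/mL for calibration backgrounds, 2–6 kBq/mL for recovery
backgrounds, a warning above ~40 MBq total in the field of view (dead-time
and pulse-pileup bias), and a ±10% default tolerance on the achieved
contrast around the 8:1 target.  QC returns flags; it never raises.

## Phantom geometry

Phantoms are declarative: a uniform cylinder (diameter, length) or a
torso-shaped body modelled as an elliptical cylinder with explicit sphere
centers and z-aligned low-density cylinder inserts.  World coordinates are
right-handed millimetres with the origin at the body centroid and z the
scanner axis.  "Noncylindrical" is a declared attribute rather than a shape
metric, since compliance concerns intent (torso-like scatter/attenuation)
rather than a computable threshold.

Built-ins: `uniform20` (200 mm diameter × 200 mm); `iq_nema` (9.7 L,
194 mm long, ellipse semi-axes 150 × 106 mm, six spheres of 10–37 mm on a
57.2-mm ring, 50-mm central cold insert); `ctn_like`, a parameterized
anthropomorphic stand-in (NEMA sphere set plus a 7-mm sphere and two
lung-like cold cylinders) — not a replica of any commercial phantom, since
exact internal dimensions are not published.

Compliance bounds are inclusive at the printed value except where the rule
is phrased as a strict excess (volume > 9 L, length > 180 mm for recovery
phantoms).  Calibration phantoms need ≥ 150 mm diameter and ≥ 200 mm
length; non-uniform phantoms are accepted for calibration with an
informational flag only.

## Simulator

The simulator stands in for acquisition plus reconstruction at desk scale;
it deliberately contains no sinogram physics, scatter, randoms,
attenuation, dead time or point-response-function (Gibbs) effects.

1. **Rasterization.**  Voxel values are volume-fraction-weighted mixtures
   of compartment concentrations.  Body and insert cross-sections are
   subvoxel-sampled in-plane at the configured factor (default 4 per axis)
   with exact 1-D interval overlap axially; sphere membership is
   subvoxel-sampled in-plane with the axial chord through each subcolumn
   intersected exactly with the voxel extent, which keeps total painted
   sphere activity within ~0.2% of (π/6)d³ at the default factor.
2. **PSF.**  Isotropic Gaussian blur with σ = FWHM/2.3548, default FWHM
   5 mm — a representative harmonized clinical reconstruction.  The blur is
   applied on the voxel grid with zero-padding; grids are sized with a
   25-mm margin so total activity is conserved to < 0.1%.
3. **Calibration bias.**  A single multiplicative factor, exactly the
   quantity the calibration analysis is supposed to recover.
4. **Noise.**  Gaussian, heteroscedastic: per-voxel σ = σ₀·√(v/v_ref), so
   variance is proportional to the local mean as in reconstructed PET
   images at clinical statistics.  Gaussian-on-image (rather than Poisson
   on counts) keeps the ground truth analytic.  Negative excursions are
   retained.  One seeded generator per simulated scan makes fixtures
   bit-reproducible.

Default grid: 2.0-mm isotropic voxels, within the recommended 1.5–2.75-mm
transaxial range.  Fixture fills synthesize assay records backwards from
the target concentration at scan time (5% residual), so the whole decay
chain is exercised rather than bypassed.

## Recovery oracle and the voxel aperture

`analytic_sphere_mean_rc(d, fwhm)` computes the mean over a sphere of the
sphere indicator convolved with the Gaussian PSF, using the closed-form
radial profile of ball⊗Gaussian integrated by adaptive quadrature.  In the
noise-free limit this equals the sphere's mean CRC at any background level:
writing the image as bkg + (sphere − bkg)·(ball⊗G), the background cancels
in the contrast normalization and CRC_mean = mean(ball⊗G) exactly.  The
implementation is cross-checked in the tests against an independent
fine-grid (0.25 mm) 3-D convolution, agreeing to < 0.1%.

A voxelized measurement adds one more smoothing stage: each voxel reports
the average over its own aperture, i.e. the continuous blurred image
convolved with a box of the voxel pitch per axis.
`predicted_voi_mean_rc(d, fwhm, voxel)` folds the box variance (voxel²/12)
into an effective Gaussian FWHM; at 2-mm voxels and 5-mm FWHM this lowers
the predicted 10-mm-sphere mean recovery from 0.522 to 0.507, and the
prediction then matches both a full-chain numeric oracle (fine-grid
convolution followed by a 2-mm box average) to < 0.5% and the simulator
pipeline's measured values to well under 2%.  Comparisons of measured mean
recovery must use this aperture-aware prediction; the pure-Gaussian value
describes an image no voxelized system produces.

A known limitation follows from the same physics: mean-VOI recovery of a
37-mm sphere at 1-mm FWHM is ≈ 0.9725 in the continuous limit (the ~3σ
surface layer of an 18.5-mm-radius ball removes ~2.7% of the mean), and
≈ 0.95 once the 2-mm aperture is included.  Mean recovery approaches 1
asymptotically in d/FWHM, but is not within 0.5% of 1 at d/FWHM = 37.

## VOI conventions

* Sphere centers are found by an iterated intensity-weighted centroid of
  background-subtracted, positively-clipped voxels in a search ball of
  radius one nominal diameter (converged at < 0.01 mm or 20 iterations).
  CT-based placement is deliberately absent: PET/CT coregistration errors
  of ~2 mm would corrupt mean measurements.
* The measurement VOI is a sphere of the exact insert inner diameter;
  membership is by voxel-center inclusion.  C_mean averages the VOI,
  C_max is its maximum voxel (first in scan order on ties).
* C_peak is the highest mean of a 1-cm³ sphere (diameter 12.407 mm) whose
  center lies inside the exact VOI, searched on a half-voxel lattice.  The
  search is implemented as eight FFT correlations with offset binary
  kernels, one per half-voxel sublattice, restricted to candidates whose
  peak sphere stays inside the evaluated neighbourhood.  For spheres of
  ≤ 13 mm the peak VOI necessarily includes background; peak values for
  those spheres are reported but physically depressed.
* An optional supersampling factor (2× per axis when enabled) refines the
  local neighbourhood by cubic-spline interpolation before extraction.
  Spline (not trilinear) interpolation is used because it adds essentially
  no further smoothing; the factor used is recorded in the output, since
  whether software supersamples before calculation is a known source of
  inter-package differences.
* Background for torso phantoms is the average of twelve 30-mm circular
  ROIs placed deterministically in the sphere-plane slice on rings at
  50–90% of the body cross-section, each clearing the wall by 10 mm and
  every sphere and cold insert by 8 mm beyond the combined radii.  This is
  a documented convention, not a standard; the ROI set is overridable.

## Calibration analysis

Slice-wise circular ROIs of diameter (phantom − 20 mm), membership by
voxel-center inclusion; per-slice bias, global (slice-averaged) bias, and
axial uniformity max|slice − global|/global are reported.  Slices whose
centers lie within 10 mm of a physical phantom end are excluded by default:
the radial margin handles the wall but not end-cap partial volume.  The
multi-position summary (for long-axial-FOV systems scanning the phantom at
several axial offsets) reports per-position global bias and the maximum
pairwise relative difference (relative to the smaller of each pair).

## Criteria engine

Criteria are data, not code: a JSON table carries tier tolerances
(tier 1: 0.05 for F-18/Ga-68, 0.10 otherwise; tier 2: 0.10 for all),
validation frequencies (quarterly for F-18/Ga-68 calibration, annual
otherwise), the per-diameter max-voxel CRC limits at contrast 8
(10 mm: 0.45–0.86, 13: 0.83–1.25, 17: 1.00–1.43, 22: 1.01–1.37,
28: 1.01–1.30, 37: 1.06–1.33) and the revalidation trigger kinds.  Bounds
are inclusive at the printed value with a 1e-12 round-off guard (0.05 has
no exact binary representation); a strict mode is available because the
exclusive reading also appears in practice.  Spheres absent from the
limits table (e.g. a 7-mm insert) are reported as informational, never
judged.

Validity windows start on the scan date; "quarterly" is implemented as +3
calendar months (day clamped at month end) and is configurable, since a
90-day reading is equally defensible.  Revalidation events (software
update, major service, Ge-68 phantom replacement, calibrator service)
truncate the window at the earliest trigger inside it.  Decisions are pure
functions of their inputs and serialize deterministically; each carries a
human-review sign-off field that automated evaluation never populates,
because artifact review by trained eyes is part of the paradigm and is out
of scope for automation.

## What the synthetic validation shows — and what it does not

Passing tests demonstrate that the analysis chain is *internally correct*:
injected calibration bias is recovered to ±0.005 (±0.01 under 5% noise),
CRC is bias-invariant to < 1e-6 while RC scales linearly, measured mean
recovery matches an independent convolution oracle to < 2%, and the RC↔CRC
conversion holds to 1e-10 on every measured curve.  They do not
demonstrate scanner-side effects the simulator omits: Gibbs overshoot
(CRC > 1) from point-response-function reconstructions, scatter and
attenuation-correction residuals, dead time, or count-starved noise on
long-lived radionuclides.  In particular, a Gaussian-PSF simulation can
never satisfy harmonized lower CRC bounds that sit above 1 for large
spheres; judging the upper/lower limit logic therefore uses synthetic
curve inputs rather than simulated images.

## Problem sizes

Simulated validations use the 2-mm default grid (≈ 160×125×120 voxels for
the torso phantom), chosen to be representative of clinical
reconstructions; a full simulate-and-analyze cycle takes on the order of a
second, and the complete test suite a few tens of seconds.
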