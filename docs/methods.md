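# Methods

This note documents the models, conventions, numerical choices and known
limitations of `plimap`.  Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Conventions

* **Mueller matrices** are real 4×4 arrays, row = output Stokes component.
  Elementary constructors emit unit-maximum-transmittance elements; the
  linear diattenuator therefore carries `m00 = 1/(1+d)` (Tmax = 1,
  Tmin = (1−d)/(1+d)), which is continuous in `d` and reduces to the
  familiar 0.5-scale ideal polarizer at `d = 1`.
* **Axis angles** are axial data: degrees on [0, 180), 0° horizontal
  pointing right, counterclockwise positive.  Every module shares this
  convention and it is stamped into all file metadata.
* The retarder angle denotes the **fast axis**.  Instruments differ on fast
  vs slow reporting; the choice is exposed as
  `plimap.mueller.FAST_AXIS_CONVENTION` rather than buried, so a user
  matching a slow-axis instrument knows to add 90°.
* Undefined angles (retardance or diattenuation below 1e−6) are NaN, not
  0: an `atan2` of numerical noise would pollute angular histograms.
  Invalid pixels are NaN everywhere and excluded from every statistic.

## Tilted-uniaxial forward model

`delta(theta_i, lambda) = (2 pi L / lambda) |n_e(theta_i) − n_O|` with
`n_e(theta_i) = n_O n_E / sqrt(n_E² sin²θ + n_O² cos²θ)`.  Assumptions,
made deliberately and kept simple:

* `L` is constant across inclination and wavelength.  In a real
  backscattering geometry the effective path follows the photon mean free
  path and is wavelength dependent; modelling that would require Monte
  Carlo transport, which is out of scope.
* Only the retardance **magnitude** is modelled — backscattering
  polarimeters are insensitive to the sign.  The birefringence sign enters
  through the axis convention instead (below).
* An optional per-wavelength multiplicative table on `|Δn|` represents
  polymer dispersion (order 10% across the visible); default is 1.

## Lu–Chipman decomposition

Factor order is fixed as `M = M_Δ · M_R · M_D`.  The diattenuator is built
from the first row; the depolarizer's 3×3 block is the signed square root
of `m′ m′ᵀ` computed from its eigendecomposition; the retarder is the
remainder `m_Δ⁻¹ m′`.  All routines are batched over leading axes so a
full image stack decomposes in a handful of LAPACK calls.

Numerical choices:

* Eigenvalues of `m′ m′ᵀ` are clamped at 1e−12; pixels needing the clamp
  (or with diattenuation within 1e−9 of 1) are flagged *degenerate* and
  marked invalid in maps rather than silently repaired, so maps stay
  rectangular and honest.
* Retardance axis: the retardance vector comes from the antisymmetric part
  of `m_R`; when `sin R < 1e−7` (half-wave neighborhood) it switches to the
  dyadic diagonal of `m_R`, which stays well conditioned at `R = π`.
* Single-matrix decomposition raises on reconstruction residuals above
  1e−6 (relative); the stack path instead marks the pixel invalid and logs
  per-wavelength failure counts, mirroring how instrument software omits
  wavelengths whose data reduction fails.

## Phase unwrapping

The inverse cosine confines recovered retardance to [0, π]; truth above π
returns as `2π − δ` with the axis flipped 90° — algebraically,
`M(δ, θ) = M(2π−δ, θ+90°)`, an identity the test suite asserts.  The
correction is mask-based: 90°±20° axial jumps along a scan axis toggle the
wrapped state (the transition station is assigned to the flagged side — an
arbitrary choice, documented here); flagged retardance is remapped on the
selected branch (`2π − R`, or `−R` signed for data mirrored around zero,
where the magnitude remains the physical value) and flagged angles shift
by 90°.  Corrected objects carry a `corrected` flag and refuse a second
pass.  Branch identification is algorithmic: the branch whose per-
wavelength ROI means decrease monotonically with wavelength wins (the
physical expectation from the forward model); ties default to `around_pi`
with an ambiguity flag, and if no branch is monotone no choice is made.
2-D masks are produced by scanning lines along a user-chosen axis; full
2-D gradient-integration unwrappers are deliberately out of scope.

## ROI analyses

* **Smoothing** uses normalized masked Gaussian convolution with `reflect`
  boundaries (a symmetric, doubly stochastic operator, so the mean over a
  fully valid frame is preserved exactly; with partial validity masks the
  preservation is approximate near mask boundaries).  Angle maps are
  smoothed in doubled-angle space (cos 2θ, sin 2θ) to respect the 180°
  period.  Default σ = 10 px.
* **Angular histograms** span [0, 180) in 36 bins of 5° (configurable),
  normalized to unit maximum; the dominant angle is the modal bin center,
  ties resolved by the axial circular mean of tied centers.  Optional
  per-pixel weights (e.g. retardance) reproduce "scaled by retardance"
  radial plots.  ROI means of angles are unweighted circular means by
  default, with weighting exposed as an option.
* **Path profiles** resample a polyline at 1 px arc spacing and average
  bilinear samples over ±width/2 along the local normal; stations whose
  transverse support is not fully valid are NaN.  Ordinary least squares
  (with slope standard error and R²) fits the trend.
* **Rotation registration** is by known stage angle (no feature matching):
  scalar maps are rigidly rotated about the chosen center with bilinear
  interpolation, angle maps are rotated in doubled-angle space and their
  values shifted by −stage angle; out-of-frame regions become invalid.
  Rotation-series retardance is fit to the axial sinusoid
  `a·cos(2(φ−φ₀)) + c` (period fixed at 180° by axial symmetry; needs ≥ 4
  orientations) and the angle means, lifted from their 180° wrap, to a
  line whose slope is expected near 1.

## Taubin circle fit

The algebraic Taubin estimator, solved by SVD of the centered design
matrix `[ (z − z̄)/(2√z̄), x, y ]`: low-bias, non-iterative, invariant
under rigid motions and equivariant under scaling (both property-tested).
Collinear or coincident points raise a degenerate-geometry error.  Point
extraction from images (e.g. OCT surface tracing) is upstream of this
module; it consumes plain (x, y) point sets.

## Synthetic phantoms: what they emulate, and what not

Scenes emulate thin plastic fibers (fiber-optic cable ~290 µm, synthetic
hair ~60 µm, monofilament ~63 µm diameter) secured over a dark,
depolarizing background and imaged at 405/442/473/532/632 nm with ~10 µm
pixels.  Defaults chosen once as the study conditions:

* medium `n_O = 1.59`, `n_E = 1.57` (polystyrene-like, Δn = −0.02,
  negative) over `L = 10 µm`, giving δ(0°, 405 nm) ≈ 3.10 rad — strong
  signal that still stays below π so noise-free recovery tests do not
  require unwrapping; wrap-specific tests raise |Δn| explicitly.
* background depolarizer diag(1, 0.2, 0.2, 0.2).
* noise: i.i.d. Gaussian on every Mueller element, scaled by the pixel's
  m00, with σ = (0.005, 0.006, 0.007, 0.009, 0.012) across the five
  wavelengths — ascending with wavelength, as phantom measurements are
  noisier at longer wavelengths.  Noisy matrices violating passivity by
  more than 5% (relative) are flagged, never repaired.
* axis convention: negative birefringence → retardance axis perpendicular
  to the local fiber tangent; positive → parallel.
* crossing preset: fibers at 60° and 90° (a shallow, chiasm-like
  crossing), the 90° fiber on top.
* overlap physics is a user-facing mode, not a hidden decision: `top`
  (highest fiber wins, the phantom/thin-section observation) or `average`
  (element-wise incoherent mean of the single-fiber matrices, the
  bulk-tissue observation).  The averaging mechanism is a modelling choice;
  real bulk averaging may arise from resolution or depth effects that this
  simulator does not resolve.

What the phantoms do **not** model — and hence what passing tests do not
show about real tissue: volumetric light transport and speckle, wavelength-
dependent penetration depth, instrument calibration residuals and the
Savart-plate reconstruction chain, spatially varying diattenuation in
tissue, and tissue inhomogeneity.  Simulated noise enters in Mueller-
element space because the pipeline's contract starts at calibrated Mueller
stacks.

Known limitation of incoherent averaging: when retardance is large and the
crossing angle wide (roughly δ·sin(2·separation) beyond the half-wave
regime), the mean of two retarder matrices decomposes to a half-wave
retarder whose axis leaves the bisector of the two fiber axes.  The
"dominant angle between the two fibers" behavior therefore holds for
shallow crossings such as the default geometry; the effect is a genuine
property of Mueller averaging, not a pipeline artifact.

## Problem sizes

Simulated frames default to 96×96 px (tests use 24–64 px) at 10 µm pitch,
chosen so every end-to-end check — including 1000-composition factor
recovery, 20-seed crossing suites and 100-seed circle-fit Monte Carlo —
runs in seconds while leaving fiber footprints hundreds of pixels wide.

## Container formats

Stacks are multi-page float32 TIFFs: 16 planes (m00…m33) per wavelength,
metadata (wavelengths, pixel pitch, angle convention, corrected flag,
seed, log) as JSON in the image description; invalid pixels are NaN in all
planes.  Maps export as one float32 TIFF per quantity per wavelength plus
a tab-separated summary and a JSON sidecar naming units and conventions.
In-memory computation is float64 throughout; 32-bit storage halves
container size and is the round-trip precision the tests assert.
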