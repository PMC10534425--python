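# Methods

This note documents the models implemented in `sfdical`, the conventions
and numerical choices behind them, and what the synthetic-data generator
(the digital twin) does and does not emulate.

## Imaging model

Camera and DMD projector are each described by a pinhole model: a 3D point
`P` in the global frame maps to a pixel via the rigid transform
`X = R·P + t`, the perspective divide `(x, y) = (X₁/X₃, X₂/X₃)`, radial and
tangential distortion applied in these normalized coordinates,

    δx_r = x (k₁ r² + k₂ r⁴ + k₃ r⁶),   δx_t = 2 p₁ x y + p₂ (r² + 2 x²)

(and symmetrically for y), and finally the intrinsic mapping
`u = fx·x + cx`, `v = fy·y + cy`. Conventions: 0-based pixel indices,
`(u, v) = (column, row)`, pixel centers at integers; the global frame is the
camera frame (camera pose = identity), z along the optical axis, lengths in
mm. Undistortion is a damped fixed-point iteration (damping 0.7, tolerance
1e-10, ≤ 50 iterations) that raises with its residual when the
coefficients are not contractive in the queried domain. Radial terms are
limited to k₁..k₃; the default fit uses two.

## Geometric calibration

A planar grid of dark circles (default 10×10, 2 mm spacing, 1 mm diameter;
three enlarged circles mark the origin and the +u/+v axes) is imaged in at
least three — by default ten — orientations and depths. Detection:
Otsu threshold, connected components, intensity-weighted centroids;
markers are separated from regular circles by area and the axis assignment
uses the image handedness (a front-facing board preserves orientation, so
`cross(u−o, v−o) > 0` in image coordinates), which also disambiguates
square grids; ordering is established by an affine seed from the three
markers refined with a homography. Projector "image points" are decoded
from the absolute phases of DMD row/column patterns sampled bilinearly at
the camera centroids: `u_DMD = φ_u / (f_col·4π/N_col)`.

Both devices are solved by planar calibration: per-view normalized-DLT
homographies, closed-form intrinsics from the homography constraints,
homography decomposition for extrinsic seeds, then a joint
Levenberg–Marquardt refinement of intrinsics, distortion and all poses
minimizing reprojection error (`scipy.optimize.least_squares`). The
projector pose is transferred into the camera frame per view
(`R_rel = R_pro·R_camᵀ`) and averaged — rotations by the quaternion
outer-product eigenvector, translations arithmetically — with the spread
reported. The calibrated volume is the bounding box swept by the target;
the reference plane passes through its center, normal along the camera
axis. Calibration queries outside this volume are masked: the model is
trusted only where it was sampled.

**Identifiability at telephoto geometry.** With a 21.6 mm field at 320 mm
the camera's full angle is ≈ 3.9°. In this regime the principal point and
the transverse pose components are nearly gauge-coupled: the solver
recovers them to machine precision on exact correspondences, but
sub-0.1 px centroid noise already moves `cx, cy` by several pixels while
leaving the reprojection RMS at the noise floor and the *predictive* model
(rays, phase–distance mapping, reconstruction) essentially unchanged.
Tests therefore check solver recovery on exact data strictly, and
image-based calibration on focal lengths, projector center, reprojection
RMS and downstream reconstruction accuracy.

## Demodulation and unwrapping

For the canonical shifts {0, 2π/3, 4π/3} the three-step closed form is
used; any other set of ≥ 3 distinct shifts goes through a linear
least-squares estimator on `I = DC + AC·cos(φ + δᵢ)`; both are exact on
noise-free sinusoids. Pixels with `AC ≤ max(1e-6, 0.01·median(AC))` are
masked rather than raising. Absolute phase uses a temporal anchor ladder:
the acquisition always includes one frequency low enough to stay within a
single 2π interval across the field (0.01 mm⁻¹ for measurements; an extra
0.01 mm⁻¹ anchor plus 0.25-period DMD patterns during calibration), and
each higher frequency picks the 2π branch nearest the scaled previous
level. Spatial unwrapping (scikit-image's reliability-sorted algorithm) is
available for maps without an anchor; disconnected valid regions are
unwrapped independently and flagged.

## Phase–distance conversion and surface geometry

Predistorted DMD patterns realize, on the reference plane, the phase field
`φ = 2π f c` with `c` the metric coordinate along the pattern axis. All
constant-phase surfaces are planes through the projector center, so the
phase at any 3D point equals the phase at the reference-plane piercing
point of the projector ray through it — and the phase field of one
frequency is an exact scalar multiple of another's, which is why a single
per-pixel cubic `l(φ)` (fitted over 10 virtual planes spanning the
calibrated volume, least squares on the normal equations, monotonicity
asserted on a 16-point grid) serves all frequencies after rescaling. A
4-plane fit interpolates exactly; the 10-plane default tracks the true
relation to < 1 µm over the 25 mm volume.

Topography uses the highest acquired frequency whose modulation survives
defocus over ≥ 50 % of the field. Normals are PCA plane normals over the
k = 16 nearest neighbors (cKDTree), oriented toward the camera
(`n·P < 0`). Local frames per point: `e_z = n`; `e_x` is the fringe-line
direction projected along the projector ray onto the surface
(`e_x = e_pat − e_pro (n·e_pat)/(n·e_pro)`); `e_y = e_z × e_x`. Angles of a
ray toward a device: `phi` is the polar angle from the normal (the
incidence/detection angle; ≈ 35° for the projector and a few degrees for
the camera on a flat sample), `theta` the azimuth of the in-surface
component measured from `e_y` and folded into (−π/2, π/2] (the scaling
factors are π-periodic in it; ≈ 0 on a flat sample).

## Frequency and intensity corrections

The angular scaling factors are

    S_∥(θ, φ) = sqrt(cos²θ + sin²φ sin²θ),
    S_⊥(θ, φ) = sqrt(cos²θ + cos²φ sin²θ),

with θ the polar angle and φ the azimuth from `e_y`: obliquity along the
fringe lines (φ = 90°) leaves the spacing unchanged, obliquity along the
fringe normal (φ = 0) compresses it by cos θ. The corrected local
frequency is

    f_corr = f_ref · S_z · S_∥(P, n) / S_∥(P, n_ref),

with `S_z = |P_ref|/|P|` the magnification between the surface point and
the reference-plane piercing point of its camera ray. The angular term is
normalized by the factor the *same point* would have with the
reference-plane orientation — a pure tilt correction, so an untilted
surface at any depth carries only `S_z` and a flat sample at the reference
plane is corrected by exactly 1. Against the twin's exact on-surface
fringe frequency this composition is accurate to ≈ 1.2 % mean (≤ 10 % at
the extreme field corners) on a 40 mm spherical cap at all three
measurement positions; `S_z` itself approximates the exact projector-fan
scaling to ≈ 0.1–1 % over ±10 mm. An optional flag additionally applies
the normalized S_⊥ factor.

Intensity is corrected by the Lambert factor
`S_Lambert = cos(θ_cam)·S_⊥·S_∥ ≈ cos(detection)·cos(incidence)`, applied
as a **normalization (division)** identically to the reference standard
and to samples. Applied this way it cancels exactly when geometries match
and removes the cosine attenuation when they differ; applied as a
multiplication it would double the orientation error instead. The product
form is itself an approximation: on diagonal tilts it deviates from the
true Lambertian cos(incidence) by a few percent, which sets the floor of
the reflectance residuals observed on strongly curved regions.

The per-pixel reference hypersurface `MTF_ref(l, f)` stores
Lambert-normalized intensities of a reflectance standard measured at 6
positions over the volume and 9 nominal frequencies in 0–1 mm⁻¹ (plus the
unwrapping anchor): the DC offset on the f = 0 row, AC amplitudes at each
nominal frequency's per-pixel corrected value. Because the corrected
frequency varies slightly with position, the grid is sheared; queries
interpolate along l within each nominal-frequency column first, then
across frequency. Node queries are exact; out-of-hull queries are masked
(default) or clamped. Diffuse reflectance follows the reference-ratio
form `R_SFD = (I_AC/S_Lambert)/MTF_ref(l, f_corr) · R_ref(f_corr)`; the DC
channel averages the analogous f = 0 ratio over all acquired frequencies.

## Forward model and inversion

The shipped forward model is the semi-infinite diffusion approximation for
sinusoidally modulated illumination:

    μ_tr = μa + μs′,  a′ = μs′/μ_tr,  μ_eff′(f) = sqrt(3 μa μ_tr + (2πf)²),
    R(f) = 3 A a′ / ((μ_eff′/μ_tr + 1)(μ_eff′/μ_tr + 3A)),

with `A = (1 − R_eff)/(2(1 + R_eff))` and
`R_eff = 0.0636 n + 0.668 + 0.710/n − 1.440/n²` (default n = 1.52,
anisotropy g = 0.6 carried as metadata). It sits behind one callable so a
higher-order radiative-transfer solution can replace it; the twin uses the
same model, making the end-to-end loop self-consistent. Fitting is
bounded least squares (trust-region reflective, finite-difference
Jacobian) over μa ∈ [1e-5, 10], μs′ ∈ [1e-3, 20] mm⁻¹, seeded by a 4×4
log-spaced coarse grid; non-convergence returns flagged best-effort
values. Maps are 16×16 binned (mask-aware block means, cells < 50 % valid
masked) before per-cell fitting.

## The digital twin

The twin renders each camera pixel by intersecting its (distorted) ray
with an analytic scene — plane, spherical cap, or the printed calibration
board — and evaluating

    I = illum · cos(θ_inc) · ½ (R_DC + R_AC · MTF_defocus · cos(φ + δ)),

with `illum` an inverse-square–times–cos⁴ projection falloff, `cos(θ_inc)`
the true Lambertian foreshortening, `R` either an albedo (board texture
with anti-aliased printed edges) or the diffusion-model reflectance
evaluated at the *exact* local on-surface frequency (computed from the
analytic phase gradient), `MTF_defocus = exp(−2π²σ²f²)` with blur width
σ = 0.03 mm per mm of defocus from the 316 mm focal plane, and optional
additive and multiplicative Gaussian noise seeded reproducibly per
fixture. Defaults mirror the tabletop geometry: 21.6 mm field at a 320 mm
reference plane, 25 mm calibrated depth, projector 380 mm away at 35°
oblique incidence with a 56.8 × 27.9 mm illuminated area, patterns of
0–1 mm⁻¹ with three shifts of 0, 2π/3, 4π/3.

Chip sizes default to 256×256 (camera) and 256×144 (DMD) — a downscaled
stand-in for 2048×2048 / 1920×1080 hardware chosen as the package's
working problem size; tests run mostly at 128×128. All metric quantities
are full scale, so angles, frequencies and correction factors are
unaffected; per-pixel noise statistics correspond to a coarser sampling of
the field than the real sensor.

**What passing twin tests do not show.** The twin has no volumetric light
transport (no subsurface point-spread blurring of the fringes), no
speckle, no projector gamma or DMD pixelization, no specular reflections,
and its defocus acts as a pure per-pixel AC attenuation rather than a
spatial convolution. Agreement of the pipeline with twin ground truth
validates the geometric/radiometric calibration logic, not the adequacy
of the diffusion model or Lambert approximation for real tissue.

## Design choices on genuinely open points

- **Angular-factor normalization.** The printed tilt-scaling composition
  leaves the normalization of S_∥ ambiguous. The raw factor equals
  cos(incidence) on the reference plane, so an unnormalized composition
  would "correct" a flat reference sample by 0.82; the implemented
  tilt-only ratio (see above) is the reading consistent with predistorted
  patterns defining f_ref on the reference plane, with the reference
  self-measurement identity, and with the exact fringe physics derived
  independently. Under it, the curvature-induced mean frequency deviation
  of the centered 40 mm cap evaluates to ≈ 8.5 % with a minimum corrected
  frequency of ≈ 0.33 mm⁻¹ over the three positions (the corresponding
  figures in the hardware study, ≈ 15 % and 0.28 mm⁻¹, are reproduced only
  by the unnormalized composition with that system's calibrated ~30°
  effective projection geometry — a reading that contradicts the
  flat-reference identity and is therefore not used).
- **Lambert direction.** Normalization by division, both sides (above).
- **Uncorrected baseline.** "Corrections off" assigns the nominal
  frequency, skips the sample-side Lambert normalization and queries the
  LUT at the reference-plane distance — the classic flat-sample
  calibration a practitioner would fall back to.
- **Unwrapping.** The cited hardware study uses a dedicated unwrapping
  scheme; this package substitutes the anchor-frequency ladder plus
  scikit-image spatial unwrapping, which changes behavior at steep edges
  and disconnected regions (flagged, implementation-defined).
- **Per-pixel polynomial evaluation** is direct Horner evaluation; no
  approximate fast-evaluation scheme is used.

## Known limitations

- Principal points and absolute working distance are weakly identified at
  the 3.9° field of view (gauge coupling with pose); downstream products
  are insensitive, but absolute `l` can carry a sub-mm bias that cancels
  between reference and sample.
- The frequency correction degrades toward the extreme field corners of
  strongly curved samples (≤ 10 % local error on the 40 mm cap), which
  dominates the few-percent tail of the reflectance residuals.
- LUT coverage ends at the outermost reference positions; samples beyond
  them are masked, so measurements near the volume boundary lose pixels.
- The inversion assumes a semi-infinite homogeneous medium; surface
  roughness and phase-function parameters are out of scope.
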