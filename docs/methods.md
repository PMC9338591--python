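# Methods

This note documents the models, conventions, parameter defaults and known
limitations of the camangle pipeline. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The alpha angle and the traversal convention

The alpha angle quantifies loss of femoral head–neck offset. In 2D (the
Nötzli construction): fit a circle to the head, find the neck's narrowest
point *nc*, and walk the bone contour **from the head apex toward the
neck**; point *A* is the first point whose distance from the head centre
*hc* exceeds the circle radius, and alpha = ∠(A–hc, hc–nc).

That traversal direction is the single most consequential convention in
the package and is applied identically in both measurement routes:

* **3D route:** the polar angle θ of the roundness map is measured from the
  head-to-neck axis direction, so the head apex is θ = 180° and the optimal
  cut θc(φ) — the largest polar angle at which the surface still departs
  from sphericity — *is* the alpha angle with no offset convention.
* **2D route:** `notzli_alpha_2d` walks the contour itself (not an
  angle-sorted sweep) from the apex; distal bone such as the shaft end can
  subtend a *larger* angle about *hc* than the head–neck junction, and a
  sorted sweep would jump to it.

Alpha is reported per half-plane (per azimuth φ ∈ [0°, 360°)), because
anterior and posterior asphericity differ clinically; a max-of-antipodal-
pair view is provided for full-plane reporting.

## Pipeline stages and tunable parameters

All thresholds live in `RunConfig` and are echoed into every result file.

| Parameter | Default | Meaning |
|---|---|---|
| `surface.smooth_sigma_vox` | 0.7 voxel | Gaussian pre-smoothing of the binary mask before iso-surfacing. Places the 0.5 level set near the true boundary: on a digital R = 20 mm sphere at 1 mm spacing the mesh area is within ~1 % of 4πR² (vs ~4 % un-tuned staircase excess at σ = 0.5). |
| `surface.head_margin` | 1.10 | Head label: vertices within this multiple of the initial head radius. |
| `surface.neck_band` | (0.8, 2.2) | Neck label: axial projection band, in head radii. |
| `surface.neck_radial_margin` | 1.2 | Neck label: maximal distance to the axis, in head radii. |
| `surface.shell_band` | (1.1, 2.0) | Shell used for the initial neck direction. |
| `geometry.ransac_iters` | 2000 | Minimal 4-point sphere hypotheses. |
| `geometry.ransac_thresh_mm` | 0.75 | Inlier threshold floor; effective threshold max(0.75 mm, 0.02 r). |
| `geometry.station_step_mm` | 1.0 | Spacing of neck cross-section stations along the axis. |
| `geometry.axis_tol_deg` / `axis_max_iter` | 0.5° / 10 | Fixed-point stopping rule for axis refinement. |
| `geometry.n_slices` | 120 | Radial half-planes over [0°, 360°); `arc180` mode gives the legacy 7-plane arc over [0°, 180°]. |
| `alpha.theta_step_deg` | 0.5° | Polar resolution of the roundness map, θ ∈ (0°, 175°]. |
| `alpha.tau_floor_mm` | 0.6 | Asphericity tolerance floor; effective tolerance max(0.6 mm, half voxel diagonal) / R. Guards against voxelization noise triggering false exceedance at ~0.6 mm imaging resolution. |
| `alpha.w_head` : `w_neck` | 10 : 1 | Asymmetric misclassification weights of the cut cost. |
| `alpha.lambda_smooth` | 2.0 | L1 smoothness penalty per θ-bin of azimuthal cut change. |

### Initial landmarks

The head centre is the global maximum of the Euclidean distance transform
(ties broken toward the lowest (x, y, z) index); its value is the head
radius. The initial neck direction is the ray from the head centre to the
centre of mass of the foreground voxels in the shell at 1.1–2.0 head radii.
A principal-component direction of that shell was evaluated and rejected:
for a proximal femur the annular shell's largest variance runs across the
bent neck-plus-shaft mass, not along the neck, and lands far outside the
refinement basin, whereas the centre-of-mass ray is within ~10° of the true
axis on phantoms — which is all the initializer must achieve, since both
the sphere and the axis are refined afterwards.

### Neck axis refinement

Cross-sections of the neck-labeled surface are taken on planes normal to
the current axis every 1 mm. A station is only trusted when its section is
a **single closed loop** (every mesh-plane intersection point shared by
exactly two face segments, one connected cycle) that wraps the axis;
partial rims at the label-band edges would otherwise masquerade as
small-circumference sections. The waist is the **first sustained
circumference minimum from the head side** — the walk stops once the
perimeter has risen 5 % above the running minimum — because an oblique cut
through the trochanteric flare or shaft further out can be shorter than the
true neck ring; anatomically the neck waist is the narrowest point *of the
neck*, and ties resolve toward the head. The refined direction runs from
the sphere centre through the waist centroid and the procedure iterates to
a fixed point (0.5°, ≤ 10 iterations, unconverged runs flagged).

### Optimal cut and sub-threshold refinement

The data term counts misclassified sampled cells: aspherical cells
(ρ > 1 + τ) on the head side of the cut cost `w_head` each, spherical cells
on the neck side cost `w_neck`. With the L1 smoothness term the circular
problem is solved exactly: a vectorized value pass over every possible
starting θ-state (O(nθ² · nφ) with the two-pass L1 min-convolution) finds
the optimal closure, then one pointer-tracking pass recovers the cut. With
λ = 0 this provably reduces to independent per-column minimization (tested
against exhaustive search), and λ → ∞ forces the best constant cut.

The raw cut localizes alpha where roundness drops below 1 + τ, which
underestimates alpha by an amount proportional to τ (≈ 2.6° at
r/R = 0.8 with τ = half a voxel diagonal). Since alpha proper is where the
surface leaves the *radius* (ρ = 1) and τ exists only to reject noise, the
cut is refined by continuing the steep aspherical branch just below it
linearly to ρ = 1. Interpolating on the spherical side instead would be
ill-conditioned (ρ hovers around 1 there, and mask smoothing slightly
fills the concave junction). The refinement moves the cut only toward the
head and at most 3°; the 2D construction applies the same continuation (to
d = r, quadratically when the contour is dense), so the two routes share
the convention and their concordance is unaffected.

## The phantom model

`FemurPhantomSpec` describes an analytic proximal femur: a spherical head
(R, default 24 mm), a cylindrical neck (r_neck < R, default 16 mm, length
30 mm) along an oblique axis, a conical trochanteric flare widening the
neck to the shaft radius over 10 mm, and a shaft cylinder leaving the flare
at the neck–shaft angle (default 130°). The flare always ends wider than
the neck (≥ r_neck + 4 mm) — real bone widens distal to the neck waist,
and without this a narrow shaft would fake a second, distal waist. Default
dimensions are adult-scale plausibility choices placing baseline alphas
(30°–53° over the tested r/R grid) inside the clinically reported range.

The cam deformity multiplies the head radius by 1 + h·w(θ, φ) inside an
angular window. The bump profile w is a flat-topped tapered-cosine (Tukey)
window in both coordinates — exactly 0 on the window boundary, raised-cosine
flanks (defaults: 3° in θ, 6° in φ), flat plateau at 1. The flat top makes
the ground truth sharp: the analytic first-exceedance angle equals
`cam_theta_max` for every azimuth strictly inside the span, and on the
plateau the deformity is fully expressed, while the surface stays
C¹-smooth. A full raised cosine (no plateau) would make any
finite-tolerance detector miss the nominal severity near the window edges,
leaving the ground truth dependent on the detector — the taper widths
bound that edge region explicitly instead. Plateau-level recovery is
therefore evaluated on azimuths at least one φ-taper inside the span.

Voxelization is a centre-in-solid test on an axis-aligned grid sized to the
phantom plus padding; it is deterministic given (spec, spacing). Optional
seeded Gaussian radial jitter (off by default) supports robustness tests.

### What the phantoms do and do not emulate

They emulate the geometry the pipeline assumes — quasi-spherical head,
narrower oblique neck, cam-type supra-spherical bone excess — at MRI-like
resolution (1 mm grids; ~0.6 mm is typical in-plane imaging resolution).
They do **not** emulate grayscale MRI contrast, segmentation errors,
cortical/trabecular structure, the acetabulum, or pathological shapes
beyond cam bumps (dysplasia, Perthes). Passing phantom tests therefore
demonstrates geometric correctness and noise tolerance of the measurement
chain downstream of segmentation, not robustness to segmentation failure.

## Agreement statistics

`icc_absolute` is the two-way random-effects, absolute-agreement,
single-measure ICC — ICC(A,1) in the McGraw & Wong taxonomy — computed from
the mean-squares decomposition, with the standard F-based 95 % CI and the
between-subjects F-test p-value. This model is the standard choice when
the same raters rate all units and systematic offsets should count against
agreement; the model name is stated in the output. Units of analysis are
hip × plane combinations (a 19-hip, 7-plane study yields n = 133); per-hip
aggregation is available behind a flag. Missing cells raise rather than
being imputed, and fewer than 5 units are refused. Reliability bands:
ICC > 0.9 excellent, ≥ 0.75 good, ≥ 0.5 moderate, else poor.
Bland–Altman uses the sample (n−1) SD and ±1.96 SD limits. Percentiles
use linear interpolation between order statistics.

The simulation helper generates two-rater tables with unit-level true
alphas ~ Normal(57°, 6°) plus independent rater noise, so the generating
ICC is σ_subject² / (σ_subject² + σ_noise²) and calibration can be checked
by recovery (the acceptance script does this with 200 tables).

## Numerical choices and degenerate inputs

* Masks must have axis-aligned (possibly flipped/permuted) affines; oblique
  affines are rejected rather than resampled — resampling a binary mask
  would blur the very boundary being measured. The canonical frame is
  right-handed +x/+y/+z, world units mm, voxel world position at its
  centre, 0-based indices.
* Coplanar RANSAC quadruples are rejected by a scaled determinant test;
  hypothesis ties resolve to the first (deterministic for a fixed seed).
* Mesh-plane contouring nudges vertices lying exactly in-plane by 10⁻⁷ mm
  to one side — symmetry planes otherwise produce inconsistent section
  topology — and chains segments on a quantized endpoint graph.
* Azimuth columns with no ray hits are flagged `extrapolated` and
  interpolated circularly from neighbours; a map missing more than 30 % of
  the clinical band θ ∈ [20°, 120°] aborts with a typed error (the
  geometry is presumed wrong).
* Degenerate inputs (empty masks, spheres without necks, unstructured
  point clouds, zero-variance paired differences) raise typed errors or
  flagged results; the CLI maps expected failures to exit code 2 with a
  structured JSON error record.

## Validation problem sizes

Phantom validation runs at 1 mm isotropic spacing with 72 radial slices
(5° azimuth grid) — fine enough that every named clinical plane lies on the
computed grid — over neck/head ratios {0.5, 0.6, 0.7, 0.8} and cam
severities {55°, 65°, 75°, 85°} (height 0.15, 60° azimuth span). The CLI
default of 120 slices matches the densest clinical reformatting; the
validation grid choice is about balanced coverage of the circumference,
and results are insensitive to it.

## Known limitations

* The cost function's exact form in deployed clinical prototypes is not
  public; this package's asymmetric misclassification term with L1
  smoothness is its own concrete instantiation (all four constants are
  config-exposed), so behavioural plausibility on phantoms — not numerical
  equivalence with any vendor tool — is what the validation demonstrates.
* The alpha angle is undefined where the bone never leaves the fitted
  circle (e.g. coxa profunda-like slices); such slices are flagged, not
  guessed.
* Whole-pipeline accuracy on real MRI depends on segmentation quality,
  which is out of scope: the pipeline's input contract starts at the
  binary mask.
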