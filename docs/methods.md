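# Methods

This note records the models, conventions and numerical choices behind
`rhizopan`, and what the synthetic-scene tests do and do not demonstrate
about real field imagery.

## Scan geometry and planner arithmetic

The imaging head is modeled as a camera with angular field of view `f`
(default 60°) whose frame covers `w × h` mm of the tube wall (default
35 × 28 mm on a 63.5 mm ID tube). One 360° *strip* consists of
`n = ceil(360/(f(1−v)))` equally spaced snaps for requested angular overlap
`v`; strips advance by a vertical step `s` (default 15 mm), giving
`floor(L/s)` strips for an imaged length `L`. Counting conventions: ceiling
for angular coverage (a partial frame is still a frame you must take),
floor for strips (the trailing partial step is not a full strip), and the
realized overlap `1 − 360/(n·f)` always meets or exceeds the request.

Manual-coverage counts treat the overlapped angular and vertical counts as
explicit inputs to a product rather than deriving both from one rounding
rule: operator-planned overlapped grids follow no single convention, so the
planner does not pretend otherwise.

The energy chain is plain arithmetic over a component load table (power ×
active seconds per cycle). Two modes exist because engineering write-ups
round intermediates: the default keeps full precision; `paper_rounding`
rounds daily energy to whole Wh, sizes the battery from the unrounded
post-conversion value, and rounds final Wh/Ah/W to whole numbers and
transfer time to whole minutes. `battery_ah(..., rounding="ceil")` gives
the minimum-capacity guarantee (`Ah · V ≥ required Wh`). Transfer time
first rounds the payload to whole megabytes, the unit link budgets are
quoted in.

Default timing (3.5 s per rotation, 2.9 s per step) puts a 66-strip tube at
419.5 s; both are configurable, as they are hardware properties.

## Synthetic tube scenes

The simulator exists so that every pipeline stage has ground truth. A
`TubeScene` is the unwrapped cylinder interior: width maps to the
circumference `π·ID` (so `width_px · mm_per_px = π·ID` within a pixel),
height to the imaged length. It contains:

- **soil**: band-limited Gaussian noise (two scales, σ = 2.5 px grain and
  σ = 9 px clumps, ±6% shading) tinted a loam color, filtered with wraparound
  in the angular axis so the seam is invisible;
- **roots**: seeded random-walk polylines with Gaussian cross-section
  (default 6 roots, 1.2 mm mean width, 50% brightness contrast, occasional
  branching), blended over the soil. Each root has its own child seed, so
  growing `n_roots` adds roots without re-rolling existing ones — this is
  what makes root-cover monotonicity testable.

The default test scene is 720 px wide (0.277 mm/px, ~92 DPI). This is a
deliberately scaled-down working resolution chosen so that full end-to-end
round trips (5 strips × 10 snaps) run in seconds; the geometry, not the
pixel count, is what the pipeline's correctness depends on.

### Camera and degradations

`render_snap` bilinearly resamples the angular window (wrapping the seam,
clamping at the tube ends) onto the sensor grid, then applies, in
acquisition order: radial barrel distortion, quadratic vignetting, a
log-normal exposure gain `exp(N(0, σ_jitter))`, specular reflection
streaks, additive Gaussian noise, and clipping to [0, 1]. The random stream
draws the same variates regardless of which strengths are zero, so two
cameras differing only in one degradation see identical realizations of the
others — the basis of several differential tests.

Reflection streaks are thin near-vertical lines (super-Gaussian cross
section, default 2.5 px ≈ 0.7 mm half-width — a thin specular reflection of
an LED strip on acrylic) that raise value, drop saturation and pull hue
toward a fixed artifact hue (default 0.83, violet). The artifact hue and
streak geometry are free simulator choices: field reports localize the
artifact in the hue plane but do not quantify it. The truth mask stored on
each snap is the region where the streak profile exceeds 0.5.

Cylindrical optics are simplified to planar unwrap + radial distortion: the
measured corrective profile of a real system lumps lens and tube-curvature
distortion into one radial profile, so the simulator generates exactly the
class of distortion the corrector removes. Focus/defocus blur is not
modeled (solved by hardware in practice), nor photorealistic soil, nor
moisture films. Consequences: passing round-trip tests demonstrate the
pipeline's geometric and photometric consistency, not segmentation-grade
realism of the imagery.

## Distortion model

`r_d = r_u (1 + k₁ρ² + k₂ρ⁴ + k₃ρ⁶)`, `ρ = r_u/r_norm`, about center
`(cx, cy)` — the standard even-order radial polynomial. The polynomial is
the forward (undistorted → distorted) map; producing a distorted image
therefore uses a numeric inverse, tabulated on a 1024-knot radius LUT with
linear interpolation, while correction evaluates the polynomial directly.
A monotonicity guard rejects profiles whose map folds inside the frame.

Calibration fits `(k₁, k₂, k₃, cx, cy)` by Levenberg–Marquardt least
squares on ≥12 point correspondences spanning ≥3 distinct radii (collinear
or single-radius geometries are rejected as rank-deficient), reporting the
RMS residual. From a grid image, dot centroids are matched to the nearest
ideal lattice point, valid while displacement stays under half the dot
spacing. A note on identifiability: over any realistic frame the ρ⁴ and ρ⁶
basis terms are nearly collinear, so under observation noise `k₂`/`k₃` are
individually ill-determined even when the fitted *mapping* agrees with
truth to a small fraction of a pixel; tests therefore check `k₁` and the
mapping, which is what correction quality depends on.

## Reflection removal

Detection thresholds a hue band (circular, may wrap through 0) with an
optional brightness gate `V ≥ v_min` (default 0.5) and saturation gate,
followed by a morphological closing (radius 1) to consolidate streaks. The
band can be fixed by the user or found automatically as the isolated
secondary mode of the hue histogram of bright pixels. In the pipeline the
automatic band is estimated **once per scan from pooled histograms**, not
per snap: the artifact hue is a property of the light source, and single
frames may contain too few streak pixels to raise a detectable mode (this
failure mode was observed directly on per-snap estimation).

Removal writes only inside the detected mask (unmasked pixels are
bit-identical). The default `interpolate` fill seeds each masked pixel from
its nearest donor and runs four 3×3 diffusion passes; donors are taken from
outside the mask *dilated by 2 px*, because the rim just outside a streak
is partially contaminated — using rim pixels as donors smears the artifact
into the fill. `clamp_hue` replaces only the hue channel (median-filtered
donor hue), keeping S and V, for workflows that must not alter brightness.

## Normalization and cropping

Exposure normalization is gain-only (rank-preserving): within a strip, snap
`i+1`'s gain matches the median Rec. 601 luminance of its left overlap to
snap `i`'s gained right overlap, anchored at angle 0; strips are then tied
through the median of their vertical overlap bands. Gains are clipped to
[0.5, 2]. With no overlap at all the code falls back to global-median
matching with a warning. Normalization runs before cropping because the
overlaps are the only cross-snap photometric anchor. Gray-world color
correction is available but off by default: scenes that are intrinsically
brown (soil) should not be forced neutral; enable it for workflows with a
neutral reference target.

Cropping keeps each snap's unique wedge (360/n degrees × step height) plus
a guard margin (default 8 px) for seam refinement and feathering. All crop
boundaries are computed in absolute panorama coordinates and rounded per
boundary, so widths telescope exactly to the panorama width and rounding
error never accumulates.

## Stitching

Registration is geometry-first: the locomotive's dead-reckoned placement is
the prior, and normalized cross-correlation over the guard overlaps refines
it by at most `search_px` (default 2) integer pixels. A candidate must beat
the prior by 0.02 NCC per pixel of deviation — without this bias, smooth
filled regions and noise can pull seams off the (highly accurate) prior;
with it, refinement only acts when the texture genuinely supports a shift.
Around the closed rotation the refined seam shifts must telescope to zero;
the residual closure error is distributed uniformly across the seams
(±1 px per seam after rounding), which conserves the strip width exactly.
Overlaps are blended with linear feathering across the guard margins (seam
effectively mid-overlap). Strips are stacked by depth, each registered to
its predecessor over the vertical guard overlap with a per-strip horizontal
roll chained from strip 0. Everything is pure integer/array arithmetic:
identical inputs give byte-identical panoramas.

Degenerate inputs: flat (zero-variance) overlaps keep the prior with a
warning and score 0; missing angle indices or non-contiguous strips raise
errors naming the gap; a whole-frame reflection mask leaves the frame
untouched (no donors) after warning.

## Edge conventions

Snap depth is the *center* of the frame, and strips start at depth 0, so
the first and last strips image half a frame beyond the tube window; the
renderer clamps rows at the scene edge. Round-trip comparisons against
ground truth therefore exclude the half-step boundary rows at each end.
The panorama's column 0 corresponds to angle −(360/n)/2 (the left edge of
snap 0's wedge).

## Problem sizes in the tests

Unit and end-to-end tests run on a 75 mm tube window (5 strips × 10 snaps,
120 × 101 px sensors) — small enough that the full suite runs in seconds,
large enough that every seam, closure and overlap path is exercised.
Calibration tests use full-sensor geometry (640 × 480, 100 dots) as a real
calibration shot would.

## Known limitations

- Translational seam refinement only; no rotation/scale/homography terms —
  appropriate while the mechanics hold snaps to sub-pixel repeatability.
- The hue-threshold cleaner assumes the artifact hue is separable from the
  scene's hue distribution; reflections that stay hue-neutral would need
  the saturation/value gates instead.
- Gain-only normalization cannot correct within-frame vignetting; residual
  vignetting shows up as a faint periodic brightness ripple.
- Multispectral snaps are rendered as luminance × band gain; no real
  spectral reflectance model is implied.
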