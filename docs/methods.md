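# Methods

This note records the modelling assumptions, parameter choices and numerical
decisions behind `canostereo`, and what the synthetic-scene tests do and do
not demonstrate about field data.

## Imaging model

Both cameras are ideal pinholes with parallel optical axes, identical
intrinsics and a baseline `b` along the image x-axis. The left camera is the
reference frame: x rightward (columns), y downward (rows), z along the
optical axis toward the ground, image origin at the top-left pixel,
0-based. After rectification a scene point appears on the same row in both
views and its disparity `d = u_left − u_right` is positive, giving
`Z = b·f/d` with `f` the focal length in pixels. The built rig is
`b = 50 mm`, `f_m = 16 mm`, pixel side `P_S = 5 µm` on a 2560 × 2048 sensor;
software 2 × 2 binning doubles the effective pixel pitch and halves `f` in
pixels, which doubles the depth-resolution step
`Δ(Z) = b·f/(d−1) − b·f/d ≈ Z²/(b·f)` (≈ 12.7 mm at 1 m for the binned rig).
The lateral ground distance per pixel is `Z·P_S·binning/f_m` (≈ 0.6 mm at
1 m binned): depth is resolved roughly twenty times more coarsely than the
image plane, the ratio being `Z/b` independent of focal length. That single
number drives most of the numerical choices below.

Rectification consumes a precomputed calibration record (relative rotation,
translation, radial distortion k1/k2); it splits the relative rotation evenly
between the cameras and aligns the new x-axis with the baseline. Estimating
calibration from checkerboards is out of scope.

The footprint (soil area) seen by an image is
`A_soil = (Z̄_W · P_S / f_m)² · A_image`, evaluated at the mean camera–wheat
distance `Z̄_W`; it is invariant to binning and ≈ 0.512 m² for the full
sensor at 1 m.

## Semi-global matching

Costs are window-summed absolute differences on the 0–255 luminance scale
(inputs are rescaled by bit depth, so 8- and 12-bit containers behave
identically), aggregated along 8 scanline directions with the standard
penalties `P1 = 8·w²`, `P2 = 32·w²` for window side `w` (default 15).
Filters, in order:

* **uniqueness** — the best aggregated cost must beat the best alternative
  outside ±1 disparity by 5 % (strictly, so exact ties — textureless zones —
  are rejected);
* **texture** — windows whose intensity variance is below 1.0 (0–255 scale)
  carry no signal and are rejected;
* **left–right consistency** — the right-view winner-take-all disparity,
  read from the same aggregated volume, must agree within 1 px; this is what
  removes the occluded band at the left image edge and half-occlusions at
  leaf rims.

Sub-pixel disparity comes from a parabolic fit through the three aggregated
costs around the minimum. The disparity search range is grown in multiples
of 16 whenever more than 2 % of valid disparities pile up in the top bin.
Hole filling interpolates invalid cells by inverse-distance weighting of up
to 8 *originally matched* cells within 12 px, requiring at least 4; because
interpolated cells are never reused as sources, filling is idempotent.

## Segmentation

Two-class (soil/leaf) mode uses per-pixel RGB and HSV on the normalized
[0, 1] scale. Three-class mode (soil/leaf/spike) adds the 7 × 7 window mean
intensity, the 7 × 7 mean squared difference to the central pixel (spike
grain vs. smooth blades), and the height predictor `p95(heights) − height`,
which is invariant to the camera–ground distance (the additive ground
constant cancels). Binary learners are RBF-kernel SVMs (`C = 10`,
`gamma = "scale"`) on features standardized with training-partition
statistics; the kernel and scaling are this package's choices. Three classes
are handled by one-vs-one learners decoded by minimum code distance (ECOC).
Samples are split 70/30 (stratified, seeded) and the held-out accuracy is
reported. Mask despeckling is a 5 × 5 median (binary) or plurality vote with
ties kept at the center label (3-class), iterated to a fixed point so the
operation is idempotent; a single pass leaves rare one-pixel boundary bumps.

## Heights

Ground depth is the 90th percentile of valid soil-pixel depths — soil is the
farthest surface and mixed border pixels bias shallow — accepted only when at
least 200 valid soil pixels are visible, otherwise a configured manual
distance is used. Heights are `ground − depth`, clipped to `[0, ground]`.
Percentiles interpolate linearly between order statistics. Spike objects are
8-connected components of the spike mask of at least 50 px; each contributes
the 95th percentile of its heights, and objects weigh equally regardless of
pixel count. The plausible-height indicator is the fraction of plant pixels
whose matched depth lies between 0.6 m below the device and the ground — a
matching-quality measure, not a trait.

## Global mesh: LAI and MTA

The plant point cloud (one 3-D point per valid plant pixel, pinhole
back-projection) is triangulated by a 2-D Delaunay over the image-plane
coordinates and lifted to 3-D — a 2.5-D height-field surface; a volumetric
triangulation would yield tetrahedra, not a canopy sheet. Faces with any 3-D
edge longer than 0.03 m (configurable) are deleted as bridges between
different leaves. Face area is half the cross-product magnitude; face tilt
is the unsigned angle between the face normal and the optical axis, folded to
[0°, 90°]. LAI divides the summed face area by `A_soil` at the *median*
matched plant depth (the median resists rim pixels mismatched onto the
ground, which drag the mean deep). MTA is the unweighted mean face tilt.

**Stair-step regime.** When depth error approaches the depth-resolution
step, per-pixel faces are either horizontal or tilted ≥ 45° (for steps equal
to the lateral spacing, exactly ≥ 45°), which inflates area and saturates
tilt. Mitigations, in increasing strength: a median filter on the depth map
(5 × 5 by default in `prepare_depth_for_mesh`), aggregate binning of the
depth map (mean of valid pixels per block), or both. For depth maps with
noise at the full resolution-step scale we recommend 4 × 4 binning before the
median, which brings the mesh vertex spacing toward the noise amplitude.
For sub-pixel matched maps the stair-step mechanism is absent, so the
pipeline defaults to a light 3 × 3 median and no extra binning — a wide
median there mainly erodes thin leaves.

Two further pipeline defaults matter for area fidelity:

* interpolation-filled cells are excluded from mesh vertices
  (`mesh_exclude_filled = True`): filled cells are occlusion guesses that
  drape "skirt" faces across leaf–ground gaps and inflate area, while they
  are perfectly fine for height maps;
* LAI is evaluated over the stereo-overlap region only (columns beyond the
  99th percentile of plant disparities): the leftmost band of the reference
  image has no right-view correspondence and can contribute neither area nor,
  consistently, footprint. At field scale this band is ~3 % of the width; at
  the quarter-scale simulation rig it is ~6 %.

## Local fitting: MTA and LAD

Square regions of interest are sampled greedily in row-major order: a row
band advances by the square size once it yields a square, by one pixel
otherwise, so squares lock onto leaves at any offset and can never overlap.
A square qualifies if every pixel is plant, has a valid plausible height and
contains no Canny edge (σ = 1.4 px; high threshold at the 90th percentile of
the smoothed gradient magnitude, low threshold 0.4 × high). Sizes fall back
30 → 20 → 10 px whenever fewer than 20 squares qualify, and only the final
size is returned.

Each ROI's back-projected points get a plane fit. The default is vertical
(z-on-xy) least squares: depth noise lives on the optical axis and can exceed
the ROI's lateral extent, in which case orthogonal total least squares
misidentifies the normal (the smallest principal component flips into the
plane) and reports ~90° tilts; vertical regression is the maximum-likelihood
fit for z-only noise. Orthogonal TLS remains available
(`method="orthogonal"`) for near-isotropic clouds; its known weakness near
vertical surfaces is irrelevant below ~85° tilt. Tilt is the angle between
the fitted plane and the horizontal, folded to [0°, 90°]; LAD is the
normalized histogram of ROI tilts in 5° classes and the local MTA their
unweighted mean. Because tilts are unsigned, noise folds upward on
nearly-flat surfaces: the local MTA of a flat target is biased high, and the
Delaunay MTA more so — tilted targets benefit from error cancellation that
flat ones cannot have.

## LAI calibration

Raw stereo LAI is inflated by the stair-step artifact and deflated by leaf
overlap; the net mapping to reference LAI is calibrated as
`lai_ref = α·exp(β·lai_stereo)`, initialized from a log-linear regression on
positive responses and refined by damped (Levenberg–Marquardt) least squares
(`xtol = 1e-10`). Goodness of fit is reported as R², fit RMSE and
leave-one-out cross-validated RMSE (explicit n refits). The exponential has
no intercept, so against a strictly proportional relation it necessarily
leaves curvature; in practice the stereo method records a positive reference
LAI even at near-zero stereo LAI (the lowest stratum is always hidden), and
at realistic measurement noise the residual curvature is statistically
invisible.

## Synthetic scenes: what they emulate, and what they do not

Scenes are built from closed-form primitives: a textured ground plane
(default 1.05 m), rectangular leaf patches with known width, length, tilt,
azimuth and optional circular-arc bow (area = width × length exactly, since
length is arc length), and ears modelled as steep (55–70°), narrow,
grain-textured patches protruding above the foliage. Ground truth — LAI,
area-weighted MTA, LAD, height fields, per-view depth and labels — is
computed from the scene description, never measured from renders. Rendering
is exact per-pixel ray casting through both pinholes (right camera at +b on
x), nearest surface wins; the epipolar geometry is exact by construction.

Textures are deterministic functions of 3-D surface coordinates
(random-phase sinusoid sums; hashed cells for spike grain), hence
photometrically identical in both views (Lambertian world). Their bands are
capped a few pixels above the render sampling rate: finer texture would alias
and decorrelate the views for a purely numerical reason, which real optics
(PSF, defocus) prevent. Defaults: leaf modulation 0.12 (wheat blades are
smooth relative to soil), soil 0.22, spike grain 0.5, and a per-leaf
brightness factor drawn from U(0.85, 1.15) — leaves differ in age and
illumination, which is what makes leaf-on-leaf boundaries visible to the
edge detector. The default simulation rig is a quarter-scale sensor
(640 × 512, 20 µm pixels) with the field baseline and lens: its pixel
footprint at 1 m (~1.3 mm) matches the binned field rig, so renders stand in
for the binned processing stage and are matched without further binning.

Not emulated: sun-angle-dependent reflections and saturation physics (a
texture-driven glint stand-in exists), wind-blur and asynchronous-capture
effects, leaf translucency and self-shadowing, curved ears, stems, and the
true aspect ratio of wheat leaves at full field resolution. Passing tests on
these scenes demonstrate the geometry and statistics of the pipeline —
depth/area/angle recovery under controlled noise, occlusion direction,
classifier mechanics — not robustness to field illumination, which the
validation-accuracy figures of real campaigns would have to establish.

Problem sizes used by the test suite and the acceptance studies (renders of
640 × 512 px, disparity ranges 64–80, 5 planar targets for angle recovery,
two sparse-canopy seeds for LAI recovery) were chosen so each study isolates
one mechanism at a precision well inside the tolerances being checked.

## Degenerate inputs and tie-breaks

Nonpositive disparities map to NaN depth, never a finite value. Collinear or
sub-minimal point sets raise (`MeshError`, `FitError`); zero-area Delaunay
slivers are dropped at mesh construction. Equal-cost matching ties fail the
strict uniqueness margin. In the 3-class plurality vote, ties that include
the center pixel's class keep it; other ties resolve to the lowest class
index. The coefficient of variation uses the population σ by default
(`ddof` exposed). Percentile computations interpolate linearly throughout.

## Known limitations

* Camera tilt relative to the ground is not corrected; heights are along the
  optical axis, and a tilted rig biases every height the same way.
* Thin structures near the matching-window size (narrow leaves, foreshortened
  ears over distant background) match poorly or not at all; the left-edge
  occlusion band is unmatchable by geometry.
* The Delaunay LAD is unusable by construction in the stair-step regime
  (faces are ~0° or ≥ 45°); only the local-fitting LAD is meaningful there.
* Mesh LAI measures the visible upper stratum; overlapping canopies are
  underestimated and require the exponential calibration against reference
  measurements.
* Azimuth angles are assumed equiprobable and are not recorded.
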