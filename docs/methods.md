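# Methods

## Model and coordinate conventions

Everything lives in a right-handed world frame with the origin at the
turntable center and +Z up along the rotation axis; lengths are
millimeters, angles degrees at interfaces and radians internally. The
physical system rotates the object while cameras stay fixed; internally we
model the equivalent *camera orbit* around a static object — a rotation of
the object by +φ about the axis is identical, for every projection, to
rotating the camera center by −φ and post-multiplying its rotation by
Rz(φ). One formulation therefore covers both "move the camera" and "move
the object" modalities.

The camera is a central pinhole with square pixels and Brown–Conrady
distortion (radial k1, k2, k3; tangential p1, p2) applied to normalized
coordinates; pixels follow the computer-vision convention (+x right, +y
down, origin at the top-left). The distortion inverse is a damped 2×2
Newton iteration, accurate to 1e−8 over at least 1.5× the sensor
half-diagonal for realistic coefficient ranges.

## Resolution planning

For a camera at horizontal distance H0 and tilt Θ, the slant distance is
H = H0/cosΘ, the height offset c = H0·tanΘ, and a table rotation of s
degrees sweeps a stereo baseline B = 2·H·sin(s/2). Planar and depth
resolution at the object are δxy = H0·δp/(f·cosΘ) and δz = H²·δp/(f·B).
The depth form is evaluated through H and B; it is algebraically equal to
H0·δp/(2·f·sin(s/2)·cosΘ). A literal substitution of H = H0/cosΘ into the
tilted-camera depth expression as sometimes printed would cancel the tilt
dependence entirely; the per-tilt design-table values follow the
level-camera formula evaluated at the slant distance, which is the
interpretation implemented here.

The effective baseline angle defaults to s = 15° (three 5° steps): it is
the single value consistent with all published per-studio depth
resolutions, and it is exposed as configuration. Golden-value comparisons
round half-up to two decimals, matching how the design tables print.

The camera planner stacks paired upper (+Θ) and lower (−Θ) cameras whose
pinhole fields of view (long sensor side vertical — the cameras are
portrait-mounted in a vertical row) jointly cover the plant height, each
upper camera paired with the lower camera viewing the same band. Published
mount heights encode additional per-camera offsets that are not derivable
from c = H0·tanΘ alone, so heights are treated as configuration inputs;
the planner's own heights come from the band-coverage geometry. If the
requested resolution is unachievable the planner raises an error carrying
the achievable δxy/δz rather than silently passing.

## Synthetic studio

The simulator stands in for the physical hardware. A scene contains:

* a **measurement bar**: two square-section pillars (half-width 25 mm) at
  ±250 mm from the axis, carrying ring-coded circular targets at exact,
  evenly spaced heights on their radial faces plus uniformly sampled
  random dots on all four faces; reference distances (vertical neighbours
  per target column and one cross-pillar span) are computed from true
  coordinates;
* **evaluation markers**: flat printed targets forming a vertical column
  (radius 80 mm spiral) plus horizontal crosses (arm radius 250 mm) at the
  top and bottom of the measured volume, so measured lengths span the
  vertical and horizontal directions out to the volume edges — where
  calibration failures appear first;
* a **parametric plant**: surface samples of a stem cylinder plus
  elliptical leaf discs at phyllotaxis spacing (137.5°), enough geometric
  structure for reconstruction and merging tests without a renderer;
* a **capture protocol**: cameras of the mid-size studio (Nikon-class
  6000×4000, 3.91 µm, 60 mm at H0 = 2300 mm, ±25°) or the large studio
  (4096×2160, 3.45 µm, 25 mm at H0 = 1520 mm, +20°/−15°), with defaults of
  72 steps of 5°, detection noise σ = 0.3 px and a 2% outlier (mismatch)
  rate — typical photogrammetric values.

Feature matching is simulated as solved: tracks are linked by point
identity and corrupted only by Gaussian noise and injected uniform
outliers. Visibility is a frustum test plus a surface-normal test with a
70° obliquity limit (features foreshorten away); no occlusion rendering is
performed. Background masks are generated analytically (cells within a
12 px footprint of any projected true point at 1/8 resolution), standing in
for the photographed mask of the real studio. Fixed seeds give
byte-identical scenes and captures.

What passing tests on this simulator do **not** show about real data:
matching errors here are unstructured outliers, not correlated mismatches;
leaves neither occlude nor move; illumination, blur and rolling shutter do
not exist. The simulator validates the geometry, calibration and
evaluation machinery, not an image-processing front end.

## Coded targets

A target is a white central disc, a dark gap (1.0–1.5 disc radii) and a
12-sector binary code ring (1.5–2.1 radii), printed white-on-black.
Identity is the cyclic equivalence class of the ring word; the code book
greedily keeps canonical 12-bit words with minimum cyclic Hamming distance
3 (18 usable IDs; all-zero and all-ones reserved), so rotation never
changes an ID and any single-sector corruption fails the exact canonical
lookup — rejected, never mis-decoded. The book also happens to be free of
mirror collisions, so a chirality mistake rejects rather than mis-decodes.

Detection: Otsu threshold → connected components → weighted-moment ellipse
(the affine map of the unit circle) → dark-gap and ring verification →
dense ring sampling with sub-sector phase search → canonical decode. The
subpixel center is the intensity-weighted centroid of the disc; for the
target sizes in scope the perspective eccentricity of the projected circle
center is far below 0.1 px, so no explicit eccentricity correction is
applied. The renderer inverse-maps pixel rays onto the target plane with
3×3 supersampling, so the perspective ellipse is exact to the sampling
grid.

## Self-calibrating bundle adjustment

The bundle estimates, simultaneously: per-camera interior orientation,
every per-(camera, step) exterior orientation, and all 3D points, by
minimizing robust reprojection error. Per-step poses are **free**
parameters — turntable accuracy is never assumed; the closed loop over a
full revolution is a diagnostic, not a constraint. Intrinsics are shared
across all steps of one physical camera (fixed focus).

* **Initialization**: poses from the nominal studio geometry via the
  turntable orbit; intrinsics from nameplate focal length with the
  principal point at the sensor center; points by linear midpoint
  triangulation of the rays (refused below a 0.5° baseline angle).
* **Gauge**: the first camera's first-step pose is frozen, and one soft
  scalar residual (weight 1000) pins the distance from that camera to the
  most-observed coded target at its initial value, fixing the scale
  direction. The solution is unique up to the similarity later resolved by
  the metric scale fit.
* **Solver**: Levenberg–Marquardt on the damped robust normal equations
  with an analytic sparse Jacobian, eliminating the 3×3 point blocks by
  Schur complement and solving the reduced camera system densely, so the
  per-iteration cost is linear in the number of points. Huber weighting
  (scale 2 px) enters by iteratively reweighted least squares; accepted
  steps have monotone non-increasing robust cost. Termination: relative
  cost decrease below 1e−12 or 100 iterations. Rotation derivatives use
  the closed-form axis-angle differential with a first-order small-angle
  fallback. (A generic sparse trust-region backend was evaluated and
  converged an order of magnitude more slowly under the robust loss, which
  motivated the dedicated solver.)
* **Default interior set**: f and k1. Narrow-field single-axis turntable
  motion is near-critical for self-calibration: the principal point trades
  off against camera tilt almost freely and wanders tens to hundreds of
  pixels under noise without harming the fit, and higher distortion orders
  are collinear with k1 over the small covered radius range. The full
  Brown set can be freed in configuration (and is exactly recoverable on
  noiseless data, which the tests exercise).
* **Outlier rejection**: after a solve, observations with residual norm
  above 4 px (≫ 3σ of the nominal noise) are dropped, tracks falling under
  two detections removed, and the bundle re-run, up to three rounds or a
  fixed point; pruning more than half of the observations aborts with a
  diagnostic.
* **Closed-loop residual**: the last-step pose is compared with the
  first-step pose advanced by the nominal (n−1)·step rotation about the
  table axis; composing estimated *relative* step rotations would
  telescope to the identity and measure nothing.

## Scale, reconstruction, masking, merging, evaluation

The least-squares metric scale s minimizes Σ(s·d_model − d_true)² over the
bar's reference pairs and is applied to all points and camera centers
about the origin, which leaves every reprojection unchanged (fit is exact
for a single pair, and equivariant: pre-scaling the model by c changes s
by 1/c).

The object (markers and plant) is then reconstructed by **forward
intersection from turntable stereo pairs**: each frame is paired with the
frame three steps later (s = 15°, the design baseline), each pair is
triangulated against the fixed calibrated cameras, and a track's pair
estimates are combined by a coordinate-wise median (robust to
mismatch-corrupted pairs). Per-camera clouds use only that camera's
detections and are computable independently — results do not depend on
camera processing order. Calibration itself uses the bar tracks only; the
bar is the calibration object.

Background masking keeps a point when it projects into mask foreground in
at least `min_votes = 2` frames (frames where it falls off-sensor do not
count against it). Merging concatenates scaled clouds and collapses points
in the same voxel to their centroid, with the voxel size defaulting to the
studio's δxy (resolution-matched deduplication) and provenance widened to
"multiple cameras" where sources differ; no point moves farther than the
voxel diagonal. Cloud combination is deliberately plain concatenation in
the shared bundle frame — no ICP — because all clouds already live in one
calibrated frame.

Length evaluation reports per-pair reconstructed-versus-true distances for
the marker rulers, with mean/std aggregates recomputable from the rows,
and the replicate protocol repeats the entire reconstruction under ten
independent noise seeds. The residual map grids each camera's sensor
(6×8 cells) over the **bar** observations only and flags cells the bar
never reached: those sensor regions could not be calibrated, which is
exactly the diagnosis for short-bar failures.

## Problem sizes used in the tests

The generator defaults are the full studio conditions (72 steps of 5°,
four or eight cameras, 200 dots, σ = 0.3 px, 2% outliers). The test and
acceptance scenes are scaled-down instances chosen once: two cameras
(the outermost upper/lower pair, whose bands overlap on the measured
volume) with 24 steps of 15° and 120 dots for the calibration-recovery and
end-to-end runs, and 36 steps of 10° with 200 dots for the noise-consistency
Monte Carlo; these sizes keep every estimate comfortably within the
asymptotic regime the claims address while the full suite stays fast. The
failure-mode analogue shrinks the bar to 20% of the measured height,
simulates a distorted lens (k1 = −0.08, k2 = 0.01), and disables distortion
estimation (the correction the truncated coverage makes infeasible) while
still self-calibrating the interior position — the configuration that
reproduces, in the simulator, the field observation that a too-short bar
degrades length accuracy by an order of magnitude and leaves the upper
sensor regions uncorrected.

## Numerical choices and degenerate inputs

Distortion inversion fails loudly outside its convergence region.
Triangulation refuses rays within 0.5° of parallel. The LM damping factor
starts at 1e−6, multiplies by 4 on rejected steps (up to 12 retries) and
divides by 3 on acceptance; exhausted damping is reported as convergence
at a stationary point. Rotations are stored as axis-angle during
optimization (no gauge redundancy) and re-orthonormalized by SVD on
export; the axis-angle round trip bounds pose reconstruction at ~1e−6°.
Masks with `min_votes` exceeding the available frames empty the cloud
(documented degenerate). Merging rejects unscaled clouds. The RMS residual
is the per-component root mean square, √(Σ(dx²+dy²)/2N).

## Known limitations

* Matching is idealized; there is no feature-extraction front end.
* No occlusion model: a surface point is visible whenever it faces the
  camera within 70° and lies in the frustum.
* The planner is a pinhole, distortion-free approximation and does not
  optimize placements or reason about occlusion.
* Principal-point and full-distortion self-calibration under pure
  turntable motion is intrinsically ill-conditioned; the package defaults
  avoid it rather than solve it. Adding out-of-plane camera motion (not
  modeled here) is the standard remedy.
* The code book holds 18 IDs at Hamming separation 3; larger studios
  needing more targets would move to a longer ring.
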