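# Methods

This note records the models, conventions and design choices behind
`cowpose`, and what the synthetic experiments do and do not demonstrate.

## Orientation model

Orientation is parameterized by yaw (about the vertical axis), pitch
(side-to-side axis) and roll (front-to-back axis), in degrees, with the
camera-frame convention x right, y down, z forward (right-handed).
Rotations compose as `R = R_y(yaw)·R_x(pitch)·R_z(roll)` — intrinsic
yaw-then-pitch-then-roll, the common head-pose convention.  The axis
names fix only which axis each angle belongs to, not the composition
order; the order is therefore a package-wide convention, documented
here and used identically by the solver, the generator and the metrics.
Recovered angles from externally produced annotations could differ from
ours by a fixed convention change.

Canonical ranges are yaw, roll ∈ [−180°, 180°) and pitch ∈ [−90°, 90°].
At |pitch| = 90° one rotational degree of freedom is lost (gimbal lock);
the tie-break is roll = 0 with yaw absorbing the free angle, applied
whenever |sin(pitch)| is within 1e−9 of 1.  Decomposition validates
orthonormality and det = +1 to 1e−9 before trusting a matrix.

## Landmark schemes

The 21-point head scheme follows the 21-landmark human-face (AFLW)
annotation scheme transplanted to cattle anatomy; the full
correspondence, including which rows are exact 1:1 matches (7 of 21)
and which are closest anatomical analogs, is committed as data.  The
published mapping table lists the same cattle label twice ("Left Eye
Right Lower Corner"); we keep both rows but disambiguate the labels
with "(medial)"/"(lateral)" so the 21 labels remain unique.

No 3D head or ear model is publicly available, so canonical coordinates
are authored here as versioned fixture data: head landmarks on a
stylized bovine head with unit front-to-back length, origin at the
landmark centroid, exactly mirror-symmetric about x = 0 (9 left/right
pairs); ear landmarks on a curved elliptical-paraboloid patch, 13
points from apex to base (apex, five medial/lateral edge levels, two
base points), unit length, deliberately non-planar.  Units are
dimensionless model units: the solver recovers scale jointly with
depth, so units affect translation only, never angles.  Schemes
round-trip through JSON so users can substitute measured models.

Each landmark carries an outward unit normal used for synthetic
self-occlusion.  Head normals radiate from a reference point placed
*behind* the skull rather than from the centroid, because every
committed landmark lies on the front (face) surface: this makes all 21
landmarks camera-facing at the frontal pose, which is also the
behavior a frontal photograph exhibits.  Ear normals are the
camera-facing normals of the paraboloid patch.

## POSIT solver

Classic DeMenthon-style POSIT, chosen over a generic nonlinear PnP
because pose-from-scaled-orthography-with-iterations is the algorithm
this toolkit exists to reproduce.  Per iteration: solve the linear pose
equations through the pseudoinverse of the centered visible model-point
matrix, normalize the two recovered rows, complete with their cross
product, project to the nearest proper rotation (SVD polar
decomposition, sign-corrected to det +1), then update the perspective
corrections εᵢ = R₃·(Mᵢ−M₀)/T_z.  Convergence: max |Δεᵢ| < 1e−6
(relative-change threshold) or 50 iterations; |εᵢ| > 10 is treated as
divergence.  Preconditions: ≥ 4 visible landmarks, and the visible
subset non-coplanar (smallest/largest singular value > 1e−3) — classic
POSIT degenerates on planar constellations, so these are rejected
loudly rather than answered badly.  Occluded landmarks are simply
excluded; how hidden landmarks were treated in manual annotation
workflows is generally unstated, and solving on the visible subset is
the neutral choice.

On noise-free perspective projections of the head scheme (focal 800 px,
depth 10 model units, |angles| ≤ 60°) the solver recovers angles to
~10⁻⁶ degree with reprojection RMSE ~10⁻⁵ px; with 2 px landmark noise
the median angle error is ≈ 2°.  A nonlinear reprojection-minimizing
least-squares refinement serves as an independent oracle in the tests;
the two routes agree to < 1e−3 degree on noiseless instances.

Default intrinsics (focal = image width, principal point = image
center) are a documented stand-in: real annotation-tool intrinsics are
unknown, and POSIT needs *some* calibrated focal length.

## Synthetic data

The generator emulates an opportunistically photographed animal:
the canonical constellation is rotated/translated, perspective
projected, perturbed with isotropic Gaussian pixel noise (annotator
jitter), and thinned by Bernoulli dropout (misses/obstructions) plus
normal-based self-occlusion (a landmark is hidden when its rotated
normal faces away from the camera).  The bounding box is the axis-
aligned hull of visible landmarks padded 5% per side — a geometric
stand-in for prose ROI definitions like "head to muzzle including the
lower jaw, excluding the neck" — and the mask is their convex hull.
Default pose ranges (±90° yaw, ±60° pitch/roll) cover the orientations
a standing animal plausibly presents; the true pose distribution of
real herd imagery is unreported, so the ranges are configurable.
Splits are 60/20/20 train/val/test by seeded shuffle, with round(n·p)
for val and test and the remainder to train.

Rasters are deliberately schematic: mask filled mid-gray (0.35), each
visible landmark a σ = 2 px Gaussian blob with rank-dependent peak
intensity (0.9 down to 0.5), max-composited so each blob center is a
local intensity maximum, zero outside the padded box.  What passing
tests on this imagery shows is that the *pipeline* (generation →
correspondence → solver → metrics → regression) is internally
consistent and that pose information survives rasterization; it says
nothing about photographic nuisances — coat color, illumination,
background clutter, left/right ear confusion — which the generator
does not model.

## Scoring functions and the toy regressor

The three pixelwise scores are implemented exactly as defined on an
h×w×c feature map: Φ(u)=1; Φ(u)=Σᵢ(uᵢ−μ)² with μ the per-cell feature
mean; Φ(u)=σ(w·u).  Aggregation is a score-weighted mean of the k
highest-scoring cells (ties broken row-major, weights renormalized to
sum 1, equal weights if all selected scores are 0) — a deterministic,
desk-scale stand-in for capsule-style aggregation, which is out of
scope because its value lives in GPU-trained weights.  The aggregate
provably lies in the convex hull of the selected features.

`ScoredPoseRegressor` embeds the scores in a minimal pipeline: local
gradient-orientation histograms (8 orientations, 8×8 px cells → an
8×8×8 feature map for a 64×64 raster), scoring, top-k aggregation
(k = 16 default), and ridge regression (α = 1) of the three angles on
the aggregated vector concatenated with the score-weighted per-cell
features.  For the learnable score, w is fitted jointly by seeded
derivative-free minimization (Powell, 120 evaluations) of the training
MSE with the ridge solve nested inside.  Everything is deterministic
given the seed.  Hyperparameters of full-scale trainings (batch 16,
learning rate 0.001, 90 epochs) are recorded for context but do not
apply to this closed-form pipeline.

The comparison experiment uses 600 train / 200 test rasters at 64×64 px
(focal 420 px, depth 10, so the head fills the frame), poses uniform in
±60° yaw, ±40° pitch, ±30° roll, 1 px landmark noise.  All three
variants cut held-out per-angle MAE by ≈ 60% relative to the
predict-the-training-mean baseline (≈ 21.5° → ≈ 8.5°).  The three MAEs
are reported in the standard ablation-grid layout; the experiment
reproduces the *structure* of a scoring-function comparison, not the
absolute MAE of any full-scale system, which would require the private
field imagery and trained detection/regression networks.

## Metrics

Box IoU uses the half-open pixel convention [x0,x1)×[y0,y1), verified
against literal pixel enumeration.  Matching is greedy in descending
confidence, one-to-one, TP iff best unmatched-truth IoU ≥ threshold
(0.5 default); this COCO-style rule covers the multi-object case while
reducing to the trivial assignment in the one-object-per-image regime.
AP is all-points interpolated (area under the precision envelope vs
recall) and equals precision at the threshold in the degenerate
single-object setting — which is why a single mAP number, not a PR
curve, is the meaningful summary there.  Mask IoU (exact polygon
areas) is provided alongside; box IoU is the default.

Pose MAE wraps each component difference to (−180°, 180°] before
taking magnitudes — unwrapped differences would corrupt the error near
±180° yaw.  Default is the per-angle convention used by human
head-pose benchmarks (so numbers are comparable to those baselines);
the printed-formula ℓ2 mode `(1/N)Σ‖ỹₙ−yₙ‖` is available as
`norm="l2"` and labeled as such.  Which convention any given published
MAE used is often ambiguous; implementing both, clearly labeled, is
the defensible position.

## Numerical choices and limitations

* Rotation checks at 1e−9; gimbal tie-break roll = 0; angles always
  degrees at public interfaces.
* POSIT: pseudoinverse via SVD; polar projection tie-broken to det +1;
  tol 1e−6, max 50 iterations, ε divergence bound 10.
* Top-k ties: row-major order (stable argsort), documented because
  aggregation details at this level have no published reference.
* Acceptance/experiment problem sizes (100 poses, 1000 round trips,
  600/200 regression, 50 loop closures) are chosen so the full
  reproduction runs in seconds on one CPU while keeping Monte-Carlo
  noise well inside the asserted margins.
* Known limitations: no lens distortion; no photometric realism in
  rasters; single-object detection focus (multi-object matching is
  implemented but mAP@[.5:.95] sweeps are not); ear scheme coordinates
  are authored, not measured from a real pinna.
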