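# Methods

`bovimetry` measures five linear body dimensions of a standing animal —
withers height, chest depth, back height, waist height and body length —
from a single 3D point-cloud scene, without contact. This note documents
the model behind each stage, the tunable parameters that matter, what the
synthetic data generator does and does not emulate, and the design choices
made where the procedure was genuinely open.

## Pipeline overview

```
scene cloud
  → conditional filter → statistical outlier removal → voxel downsampling
  → RANSAC ground-plane removal → Euclidean clustering (largest = subject)
  → [optional] cattle/other classifier gate
  → PCA pose normalization → head/tail orientation correction
  → per-point curvature estimation → surface typing → candidate regions
  → FPFH first-match landmark recognition → local refinement
  → auxiliary points → five dimensions (→ error report vs. manual values)
```

All coordinates are metric meters. Clouds are *ordered* point lists: the
first-match recognition rule is defined in terms of the stored order, so
filters preserve the order of survivors and the voxel filter emits cells in
a fixed lexicographic order.

## Preprocessing

Three filters run in a fixed order. The conditional filter crops the
working volume with closed per-axis intervals (defaults ±4 m horizontally,
−0.5..3 m vertically). The statistical filter removes points whose mean
distance to their `knn_k = 8` nearest neighbors exceeds the global mean by
more than `alpha = 1` standard deviation; ties at the threshold are kept so
the operation is deterministic. The voxel filter replaces each occupied
cube of edge `leaf = 0.02 m` by the centroid of its points. The defaults
were chosen to keep a roughly 10-thousand-point subject from a typical
scene; none of them is critical below ±50%.

## Subject isolation

The ground touches the hooves, so clustering alone cannot separate animal
from floor. A plane is therefore fitted first by RANSAC (500 seeded
3-point hypotheses, 2 cm inlier threshold, total-least-squares refit on the
winning consensus set; ties on inlier count go to the earlier iteration).
Plane inliers are removed and the remaining points are clustered by
Euclidean connectivity at `tol = 6 cm`; the largest cluster is the subject.
The fitted plane is kept: every height below is a perpendicular distance to
this plane, so a tilted sensor changes nothing.

## Pose normalization and orientation

The canonical body frame is x = body length (tail positive), y = height
(up), z = chest width, right-handed, origin at the subject centroid.
Covariance uses the 1/n normalization. When the ground plane is known
(always, inside the pipeline) the height axis is taken as the plane normal
and the length axis as the horizontal projection of the leading principal
axis: the neck/head mass pitches the raw principal axis by several degrees,
which would corrupt both the orientation rule and the length-band
coordinates, and heights are *defined* perpendicular to the ground. Without
a plane, pure PCA axes are used and the up-sign is resolved by extent
asymmetry (hooves reach much farther below the centroid than the back line
rises above it).

The x sign is fixed by the orientation rule: the half-space (split at
x = 0) whose maximum height is larger contains the withers and is the head
half; it is placed on −x by at most one sagittal mirror. This exploits the
anatomical fact that the withers tops the rump in standing cattle.

## Curvature and candidate regions

Each point's `knn = 16` neighborhood is expressed in a tangent frame whose
w axis is the local PCA normal oriented away from the body centroid (so
convex body regions get positive mean curvature), and a quadric
`w = a + bu + cv + du² + euv + fv²` is fitted by least squares. The
height-field derivatives give mean curvature H and Gaussian curvature K
through the first/second fundamental forms, and the principal curvatures
follow as `H ± sqrt(max(0, H² − K))`.

The sign pair (sign H, sign K) types the surface into eight realizable
classes (peak, ridge, saddle ridge, plane, minimal saddle, valley, saddle
valley, well). `H ≈ 0` with `K > 0` cannot occur on a real surface because
`K ≤ H²`; the classifier raises on it. Zero-deadbands default to
`0.05 / r̄` and `0.01 / r̄²` with `r̄` the mean neighborhood radius —
dimensionless thresholds scaled to the sampling resolution; note
`eps_K > eps_H²` guarantees the impossible combination can never be
produced by real principal-curvature pairs.

Candidate regions combine the curvature type with pose-free positional
priors. Positions are expressed as `t` (fraction along the length axis,
0 = muzzle, 1 = tail), `u` (height normalized per side of the centroid,
+1 = crest, −1 = hooves) and `|z|` (distance from the sagittal midline —
all six landmarks are midline features). When the feature database carries
landmark priors (it does, when built by `reference_db_from_scenes`), the
bands are centered on the reference animals' landmark positions with
half-widths `dt = 0.04`, `du = 0.08`, `dz = 0.05` (widened to 3× the
observed reference spread if that is larger). Without priors, coarse
anatomical default bands apply.

## Landmark recognition

An FPFH descriptor (3 Darboux angle features × 11 bins, each block
normalized to sum 100, support radius 0.10 m) is computed from the SPFH of
the query point plus the distance-weighted SPFHs of its neighbors. Two
implementation choices matter for stability and are deliberate deviations
from the most common variant: the query point always acts as the
Darboux-frame source (the smaller-angle source-selection rule is
discontinuous on locally symmetric patches, where sampling noise flips the
choice and with it two feature signs), and binning is linear ("soft") with
a circular θ block (the near-planar geometry that dominates a body surface
puts θ and α exactly on a hard-bin edge). With these choices the descriptor
is a continuous function of the coordinates and reproduces under rigid
motion to ~1e−12.

The feature-model database stores, per landmark, the descriptors of the
snapped landmark point and its 3 nearest neighbors on each of 3 reference
animals. The match threshold τ is calibrated from the references
themselves: each reference simulates a query from an unseen animal, and τ
is 1.2× the 90th percentile of the leave-one-animal-out nearest-reference
distances (the percentile guards against a stray reference on an atypical
sample).

Recognition follows the first-match rule: candidates are scanned in stored
cloud order and the first one within τ of any reference descriptor wins;
there is no global-best search. If nothing matches, the pipeline widens
the candidate bands once (×2) and retries; as a last resort it takes the
best-scoring candidate and logs the degradation — an occasional scan has a
locally contaminated neighborhood (e.g. the head-shoulder crevice), and a
slightly degraded landmark beats no measurement.

The matched point is then refined to the *center of its feature surface*
within 5 cm: the withers to the local height maximum, back and waist to the
highest point at their length station (a plain ball-maximum would drift
uphill along the sloping back line), the brisket to the local height
minimum, and the two body-length bumps to their local maximum of principal
curvature (coordinate extrema would slide toward the torso equator).

## Dimensions and error report

Withers/back/waist heights are perpendicular distances from the refined
upper landmark to the ground plane. The chest upper point is the highest
cloud point in a 5 cm-radius vertical cylinder through the brisket point —
3 cm, the first value considered, leaves the cylinder empty too often at
the ~2.5 cm post-voxel sampling step; chest depth is the ground-normal
distance between the two chest points. Body length is the straight 3D
distance between its two landmarks (the measurement is an oblique segment;
no projection is implied by its definition).

The error report compares automatic against manual reference values as
`100·|auto − manual| / manual`, rounded half-up to two decimals. The
manual value is the denominator; this convention is validated against all
fifteen printed cells of the bundled three-animal reference table.

## Classifier and transfer

The classifier indexes a cloud (resampled to 2^depth points after
lexicographic canonicalization, which is what makes classification
invariant to input point order) with a balanced Kd-tree built by recursive
median splits on the widest-range axis. Leaf representations are the point
coordinates; each internal node applies an affine map selected by its
(level, split axis) — shared across the level — to the concatenation of
its children, followed by ReLU; a final affine layer produces class
scores. Widths double from 8 per level, capped at 64. Training is plain
SGD (batch 4, learning rate 0.003) on the softmax cross-entropy with trees
rebuilt from fresh seeds every epoch. Prediction works on the *root
representation averaged over 5 independently seeded trees*: a single tree
is a randomized view of the cloud, and averaging the embedding removes
most of the indexing noise. Inputs are centered but keep their metric
scale — absolute size is genuine signal for the tasks this classifier
serves (a body cloud spans meters, clutter decimeters), and the shape
corpus gives each family a characteristic metric size the way real object
classes have one.

Transfer freezes all level parameters, replaces the head with a fresh
two-class map, and retrains the head on the weighted union of source
examples (all labeled "other") and target examples, with boosting-style
instance re-weighting: misclassified source examples are multiplied by
`β_src = 1/(1 + sqrt(2 ln n_src / N))`, misclassified target examples by
`(err/(1−err))^{-1}` with `err` the weighted target error rate, and weights
renormalize to sum 1 each round. Because the levels are frozen, every
example's tree-averaged root representation is a fixed feature vector
within a round, and the head is fitted on exactly the representation used
at prediction time (a head trained on noisy single-tree representations
would face a different feature distribution than it sees when predicting
on averages). The best-validation
head over all rounds is returned. Because the labeled target set is small
by construction, the training portion of the target split can be expanded
ten-fold by the rotation/mirror augmentation (validation always stays on
unaugmented held-out originals).

## Augmentation

Each silhouette expands ten-fold: the original, seven clockwise rotations
(45°…315°) about the vertical axis through the centroid, a mirror across
the sagittal plane and a mirror across the transverse plane. All nine
variants are rigid or reflecting, so every true body dimension is
preserved exactly. The rotation axis and mirror planes are choices (only
the angles are prescribed by the procedure being reproduced); the vertical
axis keeps the subject upright, which is the only orientation the rest of
the pipeline ever sees.

## The synthetic scene generator

The generator emulates a sparse ToF-LiDAR acquisition of one standing
adult beef animal with exact ground truth:

- **Body**: an ellipsoid torso (semi-axes 0.85 × 0.35 × 0.30 m, center
  0.90 m above ground) carrying a Gaussian withers ridge on the front half
  (amplitude 10 cm), a brisket bulge under the chest (4 cm), small
  shoulder and pin-bone bosses (3 cm) marking the body-length end points,
  four cylindrical legs (radius 7 cm) and a head/neck ellipsoid on the
  head side. The resulting dimensions (withers ≈ 1.30 m, body length
  ≈ 1.51 m, chest depth ≈ 0.75 m) are in the range of adult beef cattle.
- **Ground truth**: landmark positions and the five dimensions are derived
  from the generative surface functions (the withers position by numeric
  maximization of the analytic top line), so they are exact by
  construction, not estimated from the samples.
- **Nuisance structure**: a ground plane sampled at the subject's
  sensor-like spacing (~3 cm), 3 free-standing clutter objects, isotropic
  Gaussian noise (σ = 3 mm, a ToF-typical figure), and a random scene pose
  (yaw, ≤3° tilt, ±1 m translation).

What it does **not** emulate: self-occlusion (a single sensor sees one
side; the generator samples the full surface), motion artifacts, mixed
pixels at silhouette edges, reflectance-dependent noise, coat texture, and
anatomical variation beyond a uniform size jitter in the classifier
silhouettes. Passing the recovery tests therefore shows that the geometry
chain is correct and noise-stable at realistic sampling density — not that
the method is validated on live animals.

The shape-class dataset (16 parametric families: plane, sphere, cylinder,
box, saddle, torus, two-lobe, ellipsoid, cone, paraboloid, bowl, annulus,
helix, cross, wedge, stairs) stands in for a generic aligned 3D shape
corpus for classifier pre-training. Clouds vary freely in yaw with small
(5°) tilt jitter — the corpus being emulated is gravity-aligned, as are
pose-normalized silhouettes — plus ±20% scale jitter and 1% noise. The
binary transfer target uses cattle silhouettes against distractors drawn
from the clutter/ground morphology (plane patches, spheres, boxes,
cylinders): that is the negative class the classifier gate actually faces,
namely segmented clusters that are not the animal.

## Problem sizes and numerical notes

The bundled experiments run at desk scale: scenes of ~20k points
(~5k-point subjects after filtering), 32-point clouds with tree depth 5
for the shape-classification experiments, 64-point clouds with depth 6 and
a 16 × 100 source corpus for the transfer experiment, and 40 + 40 transfer
targets. The
full-scale configuration (2048-point clouds, depth 11, 1000 epochs) is
reachable through the same configuration surface but is not exercised by
the test suite. Degenerate inputs are handled explicitly: collinear RANSAC
samples are rejected, near-spherical covariance spectra raise an
axis-ambiguity warning, rank-deficient quadric neighborhoods leave a point
untyped and excluded from candidate regions, and an empty half-space makes
orientation correction fail loudly rather than guess.

## Known limitations

- Landmark recognition leans on the positional priors; FPFH alone cannot
  distinguish a back-crest patch from a flank patch (both are
  near-cylindrical at this resolution). On real scans the priors would be
  recorded from the same hand-measured reference animals that populate the
  descriptor database.
- Body length is the least stable dimension (two small bumps recognized
  independently); reference measurements show the same pattern.
- The generator's full-surface sampling makes segmentation easier than a
  single-viewpoint scan; occlusion-robust variants (multi-frame fusion)
  are out of scope.
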