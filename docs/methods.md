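# Methods

## Problem and model

The package judges whether a mandibular condyle is correctly seated in its
glenoid fossa at CBCT scan time. It deliberately operates downstream of
segmentation: the inputs are per-joint 3D label volumes (0 background,
1 condyle, 2 fossa) with physical spacing and origin in the header, one
volume per joint. The pipeline is geometry-first: the joint space is
summarised as a fixed-length vector of condyle–fossa distances along a
reference set of directions, and a small feed-forward network performs the
binary classification on that vector. Distances are measured in
millimeters, which makes the representation independent of the voxel size
of the source scan.

### Coordinate contract

Voxel indices are 0-based and address voxel centers; the world coordinate
of index (i, j, k) is `origin + (i, j, k) · spacing` (mm). Volumes must be
axis-aligned (diagonal affine / identity direction matrix); oblique
volumes are rejected rather than silently resampled. By default axis 0 is
left–right and axis 2 points superior, toward the fossa; the superior axis
is a declared convention of this package, overridable per volume, because
scanner-export orientation is not otherwise recoverable from the data this
tool consumes.

### Direction set

The ray directions emulate the 198 vertices of a reference hemi-icosphere
of radius 1 mm. The exact tessellation behind that vertex count is not
derivable from any public description, and the count matters because it
fixes the classifier's input width, so the default construction is a
spherical Fibonacci lattice restricted to the superior hemisphere: with
z_i = 1 − i/n and azimuth i·2π/φ², any n is realised exactly, the pole is
included (n = 1 degenerates to the single superior ray), and the output is
deterministic. A clipped subdivided-icosahedron construction is provided
for fidelity experiments; it can only realise particular counts
(8, 25, 89, 337, … on the closed upper hemisphere) and reports the
achievable ones when asked for anything else. The reference radius is
carried as metadata only — ray-casting is parameterised by direction, not
by vertex position.

### Ray-casting

Rays start at the condyle centroid (mean world coordinate of
condyle-labelled voxel centers) and are traversed with incremental
face-crossing (Amanatides–Woo) stepping; labels are categorical so no
interpolation is applied. The condyle exit is the first condyle →
non-condyle transition and the fossa entry the first subsequent transition
into fossa label, both located at the shared voxel face, sub-voxel along
the ray; the gap is the Euclidean distance between the two crossings.
First-crossing semantics are the minimal-gap reading; later re-entries are
ignored. Non-measuring rays are classified as: `no_condyle_exit` (the ray
never passed through condyle label), `out_of_volume` (it left the grid
while still inside the condyle), or `no_fossa` (it exited the condyle but
reached the grid boundary without entering fossa label).

Rays without a gap are imputed with a value bounded by the minimum and
maximum of the measured gaps of the same casting (recomputed per joint,
per extraction, after any perturbation). Two policies exist: `midpoint`
((min+max)/2, deterministic — always used at validation/prediction time)
and `uniform` (seeded uniform draw in [min, max] — used during training
epochs as mild stochastic regularisation). The choice of a deterministic
inference-time rule is a design decision of this package; a bounded random
assignment is equally consistent with the stated bounds.

The extraction refuses to proceed when the centroid voxel is not condyle
(highly concave masks) or when no ray measures a gap, surfacing the
condition to the caller instead of imputing silently.

### Training-time augmentation

Two augmentations apply to training folds only. (1) Contralateral
mirroring: each training volume is flipped along the left–right axis once
per fold, doubling the training sample count; mirrored copies inherit
their source joint's fold so a joint and its mirror never straddle the
train/validation boundary. (2) Rigid jitter of the hemisphere, re-sampled
every epoch per joint: translation uniform in ±2 mm per axis and rotation
uniform in ±10° per Euler axis (extrinsic X then Y then Z), after which
the features are re-cast from the perturbed origin/directions. Uniform
(not Gaussian) sampling is used because the bounds are stated as ranges.
The jitter stream is keyed by (seed, epoch, joint), so runs are exactly
reproducible. Validation features always use zero perturbation and
midpoint imputation.

### Classifier

A dense network with hidden sizes 192, 128, 64, 32; ReLU activations; each
hidden layer followed by batch normalisation and then dropout (rate 0.25);
one sigmoid output. Batch-norm momentum is 0.8 in the convention
`running ← 0.8·running + 0.2·batch` (frameworks disagree on the naming;
this update rule is the package's normative contract and is asserted in
the tests). Training: Adam; weighted binary cross-entropy with class
weights w_c = n_total/(2 n_c) entering as per-sample loss multipliers;
batch size 32; 1,000 epochs by default; a cyclic learning rate between
5·10⁻⁵ and 5·10⁻⁴ with a half-period of 2,000 optimizer iterations (the
standard unit for cyclic schedules). "Decaying triangular" is implemented
as `triangular2` — the amplitude halves after each full cycle — with plain
`triangular` available, since the decay law is otherwise unspecified. The
prediction cutoff is 0.2, boundary-inclusive on the incorrect side:
label = incorrect iff confidence ≥ 0.2. Features enter as raw millimeter
distances; an optional z-scoring flag exists but is off by default.

The network, backpropagation and optimizer are implemented directly in
numpy. At this scale (≈73k dense parameters, hundreds of samples) training
is seconds per fold on one CPU, and the explicit implementation keeps
every detail of the schedule, batch-norm contract and seeding under the
package's control.

### Labels and evaluation

Reader votes (True = marked incorrectly seated) are fused by strict
majority; the reader count must be odd so no tie rule is needed.
Incorrectly seated is the positive class everywhere, so sensitivity
measures detection of seating problems.

Cross-validation is stratified k-fold (default k = 5): within each class a
seeded shuffle is dealt round-robin, so per-fold class counts deviate from
perfect stratification by at most one, and with 85/35 labels every
validation fold holds exactly 17 correct and 7 incorrect joints. Metrics
(accuracy, precision/PPV, NPV, F1, sensitivity, specificity) are computed
from the confusion matrix both per fold and pooled over all folds — each
joint is validated exactly once, so the pooled matrix covers the dataset —
and AUC is computed by the tie-safe Mann–Whitney rank formulation
(trapezoidal integration is kept as a cross-check), reported pooled and as
the per-fold mean. Metrics with zero denominators are reported as
undefined, not zero.

`recover_confusion_matrix` inverts printed two-decimal sensitivity and
specificity back to the unique integer confusion matrix by exhaustive
search over TP ∈ [0, n_pos] × TN ∈ [0, n_neg] with half-up rounding,
erroring if zero or several matrices match; it exists so that published
summary metrics can be checked for internal arithmetic consistency.

## Synthetic phantoms

The generator stands in for clinical CBCT data. A phantom is a condyle
sphere (5 mm nominal radius) inside a fossa shell cap (inner radius 7 mm,
thickness 2 mm, polar coverage 80°), rasterised at 0.4 mm isotropic
spacing by voxel-center membership; radii are jittered ±10% per joint.
The condyle–fossa displacement magnitude defines the label: 0–0.5 mm for
correctly seated, 1.5–3.5 mm for incorrectly seated (the ranges must stay
disjoint so ground truth is unambiguous). Displacement directions are
drawn on the inferior hemisphere — clinically, an unseated condyle drops
inferiorly/anteriorly out of the fossa — and rejection-sampled against an
analytic overlap test so the solids never intersect.

Every ray gap of a phantom has a closed-form value: the condyle-exit
distance is the condyle radius, and the fossa entry is the smallest
positive root over the shell's bounding surfaces (inner/outer spheres and,
for partial caps, the bounding cone — all quadratics in the ray
parameter). This oracle is what the voxel ray-caster is validated against:
agreement within one voxel diagonal on full shells, and on capped shells
away from the rim (for rays grazing the cap rim nearly tangentially the
along-ray discretisation error is unbounded, which is a property of
voxelised geometry, not of the traversal).

What the phantoms do **not** emulate: anatomical condyle/fossa shape,
cortical-bone thickness, segmentation errors, CBCT noise and motion
artifacts, and reader disagreement. Passing the end-to-end recovery test
therefore shows that the pipeline's geometry, augmentation, training and
evaluation machinery are correct and well coupled on a separable task; it
does not certify clinical accuracy on real scans, for which the published
reference numbers (accuracy 0.80, mean fold AUC 0.87 on 120 clinical
joints) remain the relevant benchmark.

## Problem sizes and numerical choices

The shipped end-to-end checks run 120 phantoms (85/35) through full
5-fold cross-validation at 100 epochs — about a minute per seed on one
CPU — which is ample for the separable synthetic task; the 1,000-epoch
default matches the clinical protocol and remains the library default.
Small demonstrations that train for far fewer than 2,000 iterations
rescale the cyclic half-period accordingly, otherwise the schedule never
leaves the low-rate regime. Other numerics: batch-norm epsilon 1e-5;
He-normal weight initialisation; unit-norm tolerance 1e-9 on directions;
imputation bounds recomputed per casting; voxel traversal uses exact
face-crossing parameters in double precision. All randomness (splits,
augmentation, imputation, weight init, batching) flows from named streams
derived from a single master seed, making metrics JSON byte-identical
across reruns.

## Known limitations

- Axis-aligned volumes only; no resampling, registration or DICOM series
  reading.
- The hemisphere tessellation is a faithful stand-in, not the original
  mesh; whether the exact vertex layout affects classification is untested.
- Whether gaps in the original protocol were measured on meshes or voxel
  masks is unknown; this package measures on voxel masks.
- The 0.2 cutoff is fixed a priori; no per-fold threshold tuning.
- No inter-rater reliability statistics (kappa) beyond unanimity counting.
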