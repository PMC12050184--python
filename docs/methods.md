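# Methods

## Model

`radshape` implements a point distribution model of the distal radius.
Each subject's bone surface is an ordered cloud of M points in mm; after
rigid registration and nearest-neighbour correspondence every subject has
the reference's M points in the same anatomical order, and is flattened to
a 3M-vector T = (x₁, y₁, z₁, …, x_M, y_M, z_M). With N subjects the model
is the sample mean T̄ and the eigenpairs of the unbiased covariance

    S = 1/(N−1) Σᵢ (Tᵢ − T̄)(Tᵢ − T̄)ᵀ,    S φ_k = λ_k φ_k,

computed via the singular decomposition of the centered data matrix (never
forming the 3M × 3M covariance; the two routes agree to 1e-8 and the test
suite checks this). A shape is synthesized as T ≈ T̄ + Σ b_k φ_k, and a
shape's coefficients are b_k = φ_kᵀ(T − T̄). The plausibility bound is
|b_k| ≤ c·√λ_k with c = 3: the eigenvalues are variances, so the familiar
three-sigma rule lives on the √λ scale. Out-of-bound coefficients raise an
error rather than being clamped — silent clamping would hide invalid
inputs.

Key consequence used throughout: a model fitted to N shapes has at most
N−1 non-zero eigenvalues, so an 8-subject group saturates (cumulative
contribution exactly 100 %) by 10 or 15 components and a 12-subject group
by 15. The retained count t for a variance target α is the smallest t with
Σ_{k≤t} λ_k / λ_T > α (default α = 0.75).

Numerical conventions: eigenvalues below 1e-10 of the largest are treated
as rank-deficient and dropped; each eigenvector's sign is fixed by making
its largest-magnitude entry positive, so models are reproducible across
linear-algebra backends.

## Registration

Coarse alignment matches centroids and principal axes. Axis signs are
disambiguated by third moments along each axis; because an elongated bone
can be nearly symmetric along individual axes, the four proper axis-flip
combinations (and, when mirroring is allowed, a reflection about the
cloud's first principal plane) are scored by nearest-neighbour RMSE
against the reference on a ≤500-point subsample, and the best-scoring
candidate wins deterministically. Mirroring is recorded as a flag plus the
reflection plane; the stored rotation always has determinant +1.

Refinement is point-to-plane ICP: per iteration, each source point is
matched to its nearest target point, pairs farther than 2.5 mm are
rejected, and the standard small-angle linearization of
Σ ((Rp + t − q)·n)² is solved by 6×6 normal equations. Convergence is an
absolute change in mean point-to-plane error below 1e-6 mm between
iterations (the most common reading of a unit-less "convergence threshold
of 1e-6"), capped at 100 iterations. The reported RMSE is the
point-to-plane residual RMSE over accepted pairs — the quantity the
algorithm minimizes — and the 0.5 mm quality gate is evaluated on it.
Failing the gate logs a warning and marks the report; it does not abort,
since deformed (fractured) bones legitimately sit farther from a normal
reference than intact ones.

Surface normals (needed by the point-to-plane objective) come from local
PCA over k = 20 nearest neighbours, oriented away from the cloud centroid.
That orientation heuristic suits the convex-ish radius surface; it is not
a general orientation-propagation algorithm.

Voxel downsampling (default 1 mm) replaces each occupied voxel with the
centroid of its members, grid anchored at the floored minimum corner,
output ordered by lexicographic voxel index — fully deterministic.

## Correspondence

Reference-driven nearest-neighbour matching: output point j is the source
point closest to reference point j, ties broken by lowest source index. A
k-d tree accelerates the search but near-ties are re-resolved by exhaustive
scan so results are bit-identical to brute force (a tested invariant).
Many-to-one matches are allowed by default, matching the distance-minimum
definition; an optional greedy one-to-one mode exists because many-to-one
correspondence can reduce effective rank on degenerate inputs.

## Morphometrics

Six indicators from the four landmarks: AB, bc (B→C), AC, CD in mm; ALF =
angle between the supplied lunate-facet crest line and the radius long
axis; ASR = angle between the line from the sigmoid-notch midpoint
(A+B)/2 to the styloid vertex C and the long axis. Angles are reported in
[0, 180]° without folding, so direction conventions are preserved. The
long axis is the first principal axis of the cloud oriented toward a
distal hint point. The rule-based typing checks articular displacement
first (> 2 mm → Barton-type; displacement is its defining feature and no
precedence order is otherwise implied), then dorsal (> +20° → Colles-type)
and volar (< −20° → Smith-type) angulation; the sign convention is
positive = dorsal.

Group comparison runs Shapiro–Wilk per group, Levene across groups,
one-way ANOVA (F computed from the definitional sums-of-squares
decomposition, p from the F distribution) and Tukey HSD with 95 %
confidence intervals, with significance stars at 0.05 / 0.01 / 0.001.
Groups with fewer than two subjects are excluded with a warning.

## Classifier

A three-layer network on the first t standardized coefficients
Φ = (b₁/√λ₁, …, b_t/√λ_t): H = σ(WᵀΦ + B), P = σ(VᵀH + C). The outputs
are independent sigmoids, not a softmax — each class receives its own
score in (0, 1), which is what makes per-class ROC operating thresholds
meaningful. The training loss is therefore per-class binary cross-entropy
summed over classes and samples; the plain multi-label form −Σ Lᵢ log Pᵢ
is available (`loss_kind="ce"`). Standardizing by √λ_k prevents the
high-variance leading modes from dominating the input scale.

Defaults (all configurable): hidden width 10, Glorot-uniform
initialization with zero biases, learning rate 0.01, per-sample SGD in
seeded shuffled order, up to 2000 epochs, early stop when the epoch-mean
loss changes by less than 1e-6. Probabilities are clipped at 1e-12 inside
the loss. Backpropagation is hand-derived and verified against central
finite differences to relative error < 1e-5.

Prediction returns both the argmax label (ties → first class in declared
order: normal, barton, colles, smith) and the per-class binary decisions
P_i > threshold_i; the two views can disagree by design.

## Evaluation

AUC is the exact pair-counting (Mann–Whitney) definition with half-credit
ties, computed from average ranks. Per-class thresholds maximize Youden's
J over midpoints of adjacent sorted unique scores, ties resolved to the
lowest threshold. Thresholds are selected on the training folds by
default; selecting them on the test fold (as a simpler protocol might)
leaks information, and is available only behind an explicit
`leaky_thresholds` switch for comparison. Stratified k-fold assignment
deals each class round-robin after a seeded shuffle, rotating which folds
receive remainders so total fold sizes balance (43/17/12/8 over 4 folds
gives exactly 20 per fold). The report carries per-fold one-vs-rest
training AUC (the table layout of the domain literature), held-out AUC,
thresholds, accuracies and confusion matrices.

## Synthetic cohort

The generator exists because every pipeline stage needs ground truth that
real CT clouds cannot provide. The template is a stylized distal radius:
a cylindrical shaft along +z (radius 8 mm) flaring over the distal 20 mm
into an elliptical head (to ~13 mm), with a styloid protrusion at +x
(landmark C), a sigmoid-notch concavity at −x (lips A and B), and a
dorsal tubercle at +y (landmark D); total length 70 mm; points sampled
uniformly in (θ, z) from one seed.

Deformations act on the shared template, so true correspondence is known:

- Colles/Smith-type: the distal fragment (above 75 % of the length)
  rotates about the transverse axis at the osteotomy plane, dorsally (+y)
  or volarly (−y), blended smoothly over a 5 %-of-length band.
- Barton-type: the articular block (above 85 % of the length) translates
  dorsally by the displacement.

Defaults encode the study conditions: group sizes 43/17/12/8, ~2000
points, angulation 25° and displacement 3 mm (just above the 20° / 2 mm
clinical criteria), per-subject magnitudes Gaussian with 20 % spread
truncated at zero, isotropic coordinate noise σ = 0.3 mm (below the
0.5 mm RMSE gate, so registration passes by construction for normal
subjects), then a random rigid misalignment (≤ 15°, ≤ 10 mm) and a random
point permutation per subject. All of it is recorded as per-subject ground
truth and the whole cohort is bit-reproducible per seed.

What the generator does not emulate: discontinuous fracture surfaces,
comminution, cortical/trabecular texture, scanner noise structure, or
segmentation artefacts. Passing tests therefore demonstrate that the
pipeline recovers known smooth deformation modes and classifies them
robustly — not that it reaches any particular accuracy on clinical CT
data.

## Problem sizes and measured behaviour

The test suite runs the full pipeline (80 subjects × 2000 points, 4-fold
CV at F = 15) for three seeds at about a minute per seed; unit and
property tests use reduced clouds (300–800 points) and shortened training
(100–500 epochs) where the property does not depend on scale. The ANOVA
type-I calibration uses 1000 null datasets of 3 × 10 samples. On the
default cohort the pipeline reaches 0.95–0.96 mean held-out accuracy and
1.00 mean training AUC; fractured subjects register against the normal
reference with point-to-plane RMSE around 0.55–0.75 mm (above the 0.5 mm
gate, reported as warnings), which reflects genuine shape difference, not
registration failure.

## Known limitations

- The nearest-neighbour correspondence is asymmetric (reference-driven)
  and can produce many-to-one matches on noisy data.
- Normal orientation is centroid-based and would mis-orient strongly
  concave regions.
- The initial aligner requires anisotropic clouds; exactly isotropic
  inputs (equal principal variances within 1e-9) are rejected with an
  instruction to pre-align manually.
- Landmarks and the lunate-facet line are inputs, not detected; articular
  displacement for the rule-based typing is likewise an input.
- With 15 standardized features on 80 subjects the network can overfit:
  training AUC saturates at 1.0 while held-out accuracy stays slightly
  lower; the report carries both training and held-out AUC so the gap is
  visible.
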