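# Methods

This note documents the models, conventions and design choices behind
crownmorph, in the spirit of the methods documentation of statsmodels or
msprime: what each stage assumes, which knobs matter, and what the synthetic
data do and do not establish.

## Landmark model and superimposition

A specimen is an ordered set of 3D points in millimetres with three roles:
*fixed* landmarks (biologically homologous points placed on cusp tips and
fossae), *curve* semilandmarks (points on ridge/sulcus polylines whose exact
position along the curve is arbitrary) and *surface* semilandmarks (points on
the occlusal surface, arbitrary within the surface). Canonical order is
fixed, then curve (grouped per curve), then surface. Templates fix the
counts: premolars 4 + 9 + 50 = 63, first molar 4 + 51 + 210 = 265.

**Centroid size** `CS = sqrt(Σ ‖xᵢ − x̄‖²)` is the size measure; it is
rigid-invariant and 1-homogeneous under scaling. **Pairwise superimposition**
uses the closed-form cross-covariance (SVD) rotation with a determinant
correction that forbids reflections — anatomical configurations must never be
mirrored. The reported shape distance is the partial Procrustes distance
between unit-size centered configurations after optimal rotation.
**GPA** centers and scales every configuration to unit centroid size and
iterates rotate-to-mean / recompute-mean until the mean moves by less than
`tol` (default 1e-10, max 100 iterations; non-convergence sets a flag rather
than raising). The total residual is non-increasing across iterations; the
mean shape is rescaled to unit size each round.

## Thin-plate splines and bending energy

The 3D TPS interpolant uses the radial kernel **U(r) = r**, the biharmonic
fundamental-solution convention of 3D semilandmark practice. The bordered
linear system `[[K, P], [Pᵀ, 0]]` is solved per output dimension; the fitted
map interpolates exactly, its affine part spans the kernel's null space, and
the nonaffine coefficients satisfy the side conditions (zero sum,
orthogonality to the source coordinates). Because `r` is conditionally
negative definite, the bending energy is `−Σ_d w_dᵀ K w_d ≥ 0` on the
side-condition subspace; it is zero iff the map is affine and is invariant
under rigid motions of the target. Duplicated source landmarks raise a
degenerate-configuration error; an optional ridge term (default 0) is exposed
for near-singular systems at the cost of exact interpolation.

## Sliding semilandmarks

Per cycle: (a) tangent directions — one unit tangent per curve semilandmark
from central differences on the arc-length parameterization of its polyline,
and two orthonormal tangent-plane vectors per surface semilandmark from the
mean of the nearest face's area-weighted vertex normals; (b) the closed-form
tangential displacement minimizing the bending energy against the reference
(fixed landmarks immobile; the projected Hessian is solved with a 1e-10
relative jitter, falling back to least squares); (c) re-projection of curve
points to their polyline (clamping at endpoints emits a warning) and surface
points to the mesh. Default 6 cycles, applied to molars as well as premolars.
Because bending energy is invariant under affine transforms of the target,
the specimen needs no pre-alignment to the reference.

The sliding **reference** is the sample Procrustes mean of the unslid
configurations; by default the mean is refreshed once from the slid sample
and sliding repeats (config `slide_reference="mean_refresh"`; `"mean"` does a
single pass). Exact cycle-to-cycle monotonicity of the tangent-step energy is
not guaranteed — each tangent step starts from the re-projected
configuration — but on smooth fixtures the sequence is monotone to well under
1% and the final energy agrees with an independent grid search to a few
percent.

Mesh nearest-point queries prune candidates with a KD-tree over triangle
centroids (k = 24) before an exact, vectorized point–triangle distance test;
on the meshes used here this is exact (verified against an all-faces scan)
and removes the need for an R-tree dependency.

## Shape PCA and predictors

Per tooth, the flattened aligned coordinates are centered and the covariance
matrix (not correlation — coordinates share units) is eigendecomposed via
SVD. Components use a deterministic sign (largest-magnitude loading
positive). The predictor table concatenates the leading 30 PC scores per
tooth plus `ln(CS)` per tooth: 93 columns for three teeth. To prevent
leakage, PCA is fitted on the training partition only and test specimens are
projected onto the training components; predictors are standardized by
training-set mean/sd before network training. Both choices are config
switches with these defaults.

## Classifier

The network is 93 → h → 1 with logistic activations throughout. "Three
hidden layers" in the source toolchain's terminology maps to **three hidden
units in a single hidden layer**: the caret/nnet stack fits single-hidden-
layer networks where size and decay are the tuned parameters, so that is the
default topology here (h and decay are free parameters). The objective is
summed binary cross-entropy plus `decay × Σ weights²` (biases are not
penalized); note this is the nnet convention, under which decay = 0.1 is a
mild penalty — applying 0.1 to a per-observation mean loss would be n-fold
stronger and collapses the net. Training is seeded minibatch SGD
(lr 0.05, batch 8, 500 epochs by default); whenever the full-data loss
increases, the epoch is reverted and the learning rate halved, so the
recorded loss history is non-increasing and training is bitwise
reproducible under a fixed seed. Tuning uses stratified k-fold (k = 10)
cross-validation over a (hidden, decay) grid; ties select the smallest
hidden size, then the smallest decay. The classification threshold is 0.5
with ties to the positive class, and the positive class is "female"
throughout. Predictor importance uses the Garson connection-weight
decomposition rescaled so the top predictor scores 100.

## Evaluation conventions

The confusion-matrix panel follows caret's `confusionMatrix`: exact
Clopper–Pearson 95% CI for accuracy; one-sided exact binomial test of the
correct count against the no-information rate (the majority-class
proportion); Cohen's kappa from the marginals; McNemar's chi-square on the
discordant counts with continuity correction. Ratios with zero denominators
are reported as NaN, never 0. ROC curves sweep the unique scores and AUC is
the trapezoid integral (equal to pairwise concordance).

**Repeatability** jointly re-superimposes both digitization rounds and
splits shape variance by a two-level Procrustes ANOVA: with n specimens and
r = 2 rounds, `MS_within = SS_within / (n(r−1))`,
`MS_among = r·Σ‖m̄ᵢ − m̄‖² / (n−1)`, `σ²_w = MS_within`,
`σ²_a = (MS_among − MS_within)/r`. The error share is `σ²_w/(σ²_a+σ²_w)` and
the agreement coefficient is its complement (an intraclass-style quantity on
the 0.9x scale typical for careful digitization). The estimator's small
negative bias from the 7 similarity parameters absorbed per configuration is
well under the reporting precision at the noise levels of interest.
**Size dimorphism** uses a Welch two-sample t test on `ln(CS)`; a degenerate
zero-variance input returns p = 1 (equal means) or 0 rather than NaN.

## Synthetic data: what it emulates, and what it does not

`make_reference_crown` builds each tooth as an analytic height field over an
elliptical crown outline: a dome plus a marginal-ridge ring plus 2 (premolar)
or 4 (molar) Gaussian cusps. Fixed landmarks are found numerically (cusp
apices; premolar fossae as minima along the central groove), curves are
quadratic arcs between cusps lifted onto the surface (molar curve counts are
allocated to the 11 named curves proportional to arc length; the premolar's
9 curve points split 5 mesial / 4 distal), and surface semilandmarks follow
a sunflower layout projected onto the triangulated mesh.

`generate_cohort` displaces the reference by ± half the **shape effect**
along a fixed smooth TPS deformation field (one field per tooth, so the
dimorphic signal is a coherent shape difference rather than independent
landmark jitter), adds a smooth per-specimen individual deformation, adds
per-landmark digitization noise re-projected onto the geometry, scales by a
log-normal sex-specific size and applies a random rigid motion. Defaults are
the study conditions: 115 F / 115 M, three teeth, male/female mean size
ratio 1.04, individual shape scale 0.08 mm, size log-sd 0.04, digitization
sd 0.008 mm (chosen so the measurement-error share of shape variance is
~1%, the regime of careful intraoral-scan digitization), and a shape effect
calibrated so the between-sex Procrustes distance is 1.5× the median
within-sex distance.

What passing tests therefore show: the *pipeline* is correct (oracle-verified
morphometrics, leak-free training, calibrated null behaviour, dose-response
in the effect size, recovery of known variance shares). What they do not
show: performance on real dentitions. The generator does not imitate real
enamel anatomy beyond cusp/fossa topology, scanner artifacts, wear, operator
idiosyncrasies or between-tooth correlation of individual shape variation —
under the calibrated synthetic conditions the classifier is near-perfect at
study scale, which should be read as "the signal put in is recovered", not
as a forecast of clinical accuracy.

## Problem sizes used by the test suite and acceptance script

Simulation-backed checks are sized to single-CPU runs: the null-calibration
study uses 20 replicate first-premolar cohorts of 50 + 50 with single-pass
sliding (38 F / 37 M training); the signal-recovery study uses 20 three-tooth
cohorts of 40 + 40 (30 + 30 training, 10 + 10 test) with single-pass sliding
and a two-point CV grid; the repeatability-recovery study uses 200 replicates
of 30 specimens × 2 rounds in shape space. The acceptance script runs the
full 115 + 115 cohort with the default one-refresh sliding protocol and the
84/90 vs 31/25 split. These sizes are the package's own choices for routine
verification; all are parameters, not limits.

## Known limitations

- Sliding assumes reasonably smooth, well-triangulated crown meshes; no mesh
  repair is attempted and degenerate faces are silently dropped.
- The repeatability estimator assumes exactly two rounds and a common joint
  superimposition; rater effects beyond round-to-round noise are not
  modelled separately.
- Template anatomy (which cusp is which) is supplied by the template or
  generator, never inferred from the mesh.
- The TPS solver is dense (fine up to a few hundred landmarks per
  configuration; the molar's 265 points are well within range).
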