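# Methods

## Data model and coordinate conventions

A contour reading is an ordered list of ≥ 4 planar vertices in a y-up
Cartesian millimetre frame, closed implicitly (the first vertex is not
repeated), oriented counter-clockwise, with K strictly increasing fiducial
indices marking anatomically prescribed loci (on the formation, stem,
choroid fissure and temporal horn boundaries; K = 4 by default — the number
is not fixed by the source material, so it is configurable).  Clockwise
input is flipped on load, keeping the start vertex and remapping fiducials.
Pixel-space annotations are converted by multiplying by the isotropic pixel
spacing and flipping the y axis, so the analysis never depends on image
display conventions.

## Contour regularization

Hand tracings differ in vertex count and spacing, so raw vertices carry no
correspondence.  Each contour is interpolated by a closed C² cubic spline
(chord-length knots, periodic end conditions; consecutive duplicate vertices
are collapsed with a warning).  Arc length is accumulated by 8-node
Gauss–Legendre quadrature of the spline speed on a fine grid (30
subintervals per knot interval) and inverted through a monotone PCHIP
interpolant refined with two Newton steps; inversion error is ≲ 1e-12 of
the total length, comfortably within the 1e-8 relative tolerance adopted for
arc-length computations.

Resampling places N = 20 control points: traversal starts at fiducial 0
(the most superior marker in the synthetic data) and runs counter-clockwise;
each fiducial is pinned to a fixed output slot, and the points between two
consecutive fiducials are equally spaced in arc length.  Slots are assigned
once per cohort from the cohort-mean arc-length fractions of the fiducials
(`slot_k = round(N · mean fraction)`, repaired to be strictly increasing)
and then frozen, because point-to-point correspondence requires identical
slots in every shape.  Note that equal *arc* spacing implies equal *chord*
spacing only on constant-curvature segments; the tests check chord equality
on circles and arc equality in general.

## Alignment

Generalized Procrustes analysis: every shape is centred and fixed at unit
centroid size (RMS distance of points to centroid = 1), then iteratively
rotated (closed-form SVD solution, determinant forced +1 so reflections are
impossible) into the evolving mean, which is re-estimated and renormalized
until it moves < 1e-10 per iteration (cap 100, warning on non-convergence).
Because every shape stays on the unit-size sphere and both steps increase
the summed inner product with the mean, the sum of squared distances to the
mean is non-increasing across iterations.  A final rotation-only pass
against the converged mean makes each aligned shape the exact
superimposition onto the reported mean.

Scale is removed deliberately: head size is a known confounder of
single-slice hippocampal measurements, so group differences are expressed
through pure shape.  The rotational gauge is fixed intrinsically — the mean
is rotated into its principal-axis frame, with the 180° ambiguity resolved
by the sign of the third moment along the major axis — which makes the
aligned set invariant (to 1e-8) under any common similarity transform of
the inputs.  An orientation-anchored gauge (e.g. "align to the first
shape") cannot satisfy that invariance, which the test suite checks
explicitly.  Pairwise `align_pair` keeps the full similarity (with scale)
for general use.  Tangent-space projection and a mirror-to-common-frame
utility exist but are off by default; the pipeline models raw aligned
coordinates, and the two hippocampal sides are always modelled separately.

## Shape model

The point-distribution model is a PCA of the aligned shape vectors about
their mean, computed through the SVD of the centred data matrix (stable when
2N exceeds the sample count); eigenvalues use divisor n − 1, eigenvector
signs are fixed so each mode's largest-magnitude component is positive, and
the basis is truncated to the smallest M whose cumulative eigenvalue
fraction reaches the requested level (default 0.95).  Projection and
synthesis are the exact adjoint pair `b = Pᵀ(x − x̄)`, `x = x̄ + P b`, so
full-mode reconstruction is an identity to 1e-9.  Mahalanobis distances
between parameter vectors weight each mode by its eigenvalue, excluding
numerically null modes (λ < 1e-12·λ₁).

## Consensus of repeated readings

Readings are averaged in model space: project each aligned reading onto the
leading M modes (the same truncation later fed to the classifier — whether
full or truncated vectors were averaged originally is unstated, and
truncated averaging keeps the consensus consistent with the classifier
features), average, and back-project.  The mean is two-stage — repeats
within a reader first, then across readers — so a reader who traces three
times does not outweigh one who traces twice.  Because the consensus is a
point in the model's span, it remains anatomically plausible even when the
raw Cartesian mean of discordant tracings self-intersects; the tests
construct exactly such a case.

## Classification and the mode sweep

Labels are encoded control = −1, subject = +1; a decision value of exactly
zero maps to control.  The SVM uses the affine kernel K(s) = γs + β with
γ = 1, β = 0 (pure linear kernel — higher-order kernels brought no benefit
in the source evaluation) and soft-margin cost C = 1.  Features are
standardized to zero mean and unit variance on the training set before the
kernel: mode coefficients of unit-size shapes are O(0.01–0.1), far below
the unit functional margin, and an unscaled C = 1 SVM on them degenerates
toward majority-class prediction; attribute normalization is also the
long-standing default of the SVM toolkits this protocol comes from.
Support vectors, dual coefficients and bias are stored openly and the
decision function is recomputed from them (tested against an independent
SVC fit).  Training rows are canonically sorted first, making results
independent of presentation order.

`mode_sweep` retrains for M = 1..M_max (default 10) and records confusion
counts and metrics per M.  Resubstitution (training = evaluation set) is the
default protocol because that is how the original evaluation was run — it
is optimistic, and reports are labelled accordingly; a seeded stratified
5-fold alternative is provided.  `select_optimum` maximizes the mean of the
ten per-class indices (sensitivity, specificity, precision, accuracy, F
over both class views), breaking ties toward the smallest M; a
`first_convergence` rule (smallest M within 0.005 of the best) is also
available.

## Evaluation conventions

Counts are kept for two class views (controls-as-positive, C, and
subjects-as-positive, S).  The reporting convention mirrors correct counts
(TN of a view equals its TP; FP of one view equals FN of the other); this is
the only bookkeeping under which the published per-class metric tables are
internally consistent, and it is what the golden-file test reproduces row by
row.  A standard convention is available behind a flag.  Overall statistics:
percent correct; Cohen's kappa of the 2×2 contingency; MAE = mean 0/1 loss
and RMSE = √MAE; RAE and RRSE normalize these by a prior-probability
(ZeroR-style) baseline.  That baseline reproduces the published relative
errors only approximately (9.545% vs a printed 9.5395%), so they are
reported but not asserted.  0/0 ratios are reported as 1.0 with a warning
(they occur only in degenerate fixtures).

The conventional-metric benchmark computes each subject's formation area by
trapezoidal integration of the closed contour (algebraically the shoelace
formula), averages readings per subject in area, fits a Gaussian per group,
and counts the subjects misclassified by the two-Gaussian likelihood-ratio
rule — the "ambiguous" cases a pure area criterion cannot call.

## Synthetic cohort

The generator emulates the study conditions: 30 controls and 33 early-AD
subjects, 3 readers, 2–3 repeats per reader per side, 20-point closed
contours with 4 fiducials.  The template is an analytic comma-shaped outline
from an elliptical body (semi-axes 7.5 × 4.5 mm, a realistic coronal
cross-section scale) with a smooth radial notch for the choroid fissure
(depth 2.5 mm at the control mean, angular width 20° at the inferomedial
position).  Two latent factors deform it per subject, drawn from per-group
Gaussians: formation height (control 1.0, AD 0.85, sd 0.05) multiplies the
superior height inside a 75° window, and fissure width (control 1.0, AD
1.20, sd 0.07) scales the notch depth.  Geometric amplitudes were chosen so
the two stated factors dominate the shape variance, as the leading modes do
in the real study.  Each reading adds: vertex re-jitter along the curve
(±30% of the spacing; fiducials stay put), smooth correlated reader noise —
a 2-harmonic Fourier displacement along the radial direction with pointwise
sd 0.4 mm, because hand tracings err in sweeps rather than independently per
point — and a similarity pose (translation sd 2 mm, rotation sd 0.1 rad,
log-scale sd 0.05).  The right side is the mirrored curve with independent
noise and its own model.  All randomness derives from one seed through named
substreams (per subject, per reading), so any slice of a cohort regenerates
stably.

**What the synthetic cohort does not emulate.**  Real tracings have
reader-specific systematic biases, non-Gaussian outliers (visible in the
original scatter plots), partial-volume and windowing effects, and genuinely
asymmetric left/right anatomy; the generator has none of these.  Passing
tests therefore demonstrate that the pipeline recovers the statistical
structure it assumes — not that the published clinical accuracies would be
reproduced on new data.  Resubstitution accuracies in particular are
optimistic by construction.

**Latent coupling.**  Because both factors shift with disease, they are
correlated across the cohort (r ≈ −0.68 at the default effect sizes).  The
dominant eigenmode is then their combined "disease axis", and no single
mode coefficient can isolate either factor (the attainable single-mode
correlation is capped near 0.92).  Recovery is therefore scored two ways:
the best single-mode |r| (which reaches ≥ 0.9 when the factors are
uncoupled and noise is low) and the multiple correlation with the leading
five modes (≥ 0.95 under the default conditions), which is the right
question to ask of a truncated linear model.

## Numerical choices and degenerate inputs

Spline arc-length tolerance 1e-8 (achieved ≈ 1e-12); GPA tolerance 1e-10,
cap 100 iterations; SVM QP tolerance 1e-6; eigen-null threshold
1e-12·λ₁; duplicate contour vertices collapsed with a warning; fewer than
4 distinct vertices, degenerate (single-point) shapes, single-class
training sets, and mismatched dimensions raise errors naming the offending
record where applicable.  Model containers and cohort files serialize
floats at full precision and round-trip exactly.

## Known limitations

- The pipeline operates on a single 2D slice; no volumetric information.
- Correspondence quality is bounded by the fiducials: if readers place a
  fiducial on different structures, the error propagates into the model.
- The consensus assumes the model span is trustworthy; with very few
  training shapes the truncated span itself is noisy.
- Resubstitution is kept as the default evaluation for fidelity to the
  original protocol, not as a recommendation; use the k-fold mode for any
  honest generalization estimate.
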