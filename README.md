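# hippomorph

Statistical shape analysis of hippocampal outlines for early Alzheimer's
disease screening from CT delineations.

## The problem

On a single coronal CT slice, early AD shows up as subtle changes in
hippocampal morphology — the formation loses height and the choroid fissure
widens — but simple scalar measurements (formation height or area) are
confounded by head size, reference-axis choice and reader disagreement.
This package implements a morphometric pipeline that works on the *shape* of
a hand-drawn hippocampal contour instead:

1. **Regularization** — each closed hand-drawn outline (with anatomical
   fiducial markers) is fitted with a periodic cubic spline and resampled by
   arc length into N = 20 corresponding control points anchored at the
   fiducials, giving the shape vector
   `x = [x1, y1, ..., xN, yN]ᵀ` (40 degrees of freedom).
2. **Alignment** — generalized Procrustes analysis removes translation,
   scale and rotation, leaving pure shape.
3. **Shape model** — PCA of the aligned vectors yields the point
   distribution model `x = x̄ + P b`; truncation to the leading M modes
   (by cumulative explained variance) gives compact shape parameters `b`.
4. **Consensus** — repeated readings per subject are averaged *in model
   space* and back-projected, which stays anatomically legal even when the
   raw coordinate average of discordant tracings self-intersects.
5. **Classification** — a linear-kernel soft-margin SVM,
   `f(x) = sgn(Σᵢ αᵢ yᵢ K(xᵢ·x) + b)` with `K(s) = γs + β`, separates
   controls from early-AD subjects on the first M parameters; a sweep over
   M with the study's metric conventions locates the operating optimum.

The clinical cohort behind the original study is not publicly deposited, so
the package ships a first-class synthetic generator that emulates the study
design: 30 controls + 33 early-AD subjects, 3 readers with 2–3 repeated
tracings per hippocampus and side, group effects expressed through
formation height (×0.85 in AD) and choroid-fissure width (×1.20 in AD),
plus pose jitter and smooth correlated reader noise.

The package is aimed at researchers in medical image analysis and
morphometrics who want a reproducible, tested reference implementation of
this pipeline, with scikit-learn-style estimators
(`ProcrustesAlignment`, `PointDistributionModel`, `ShapeSVC`) that compose
with standard tooling.

## Worked example

```python
import hippomorph as hm

config = hm.SimulationConfig(seed=1)          # study-scale synthetic cohort
report = hm.recovery_experiment(config, M_max=10)
left = report["sides"]["left"]
print(left["modes_for_95pct_variance"])       # 4
print(left["optimum_M"])                      # 5
print([round(a, 3) for a in left["accuracy_curve"]])
# [0.984, 0.984, 0.984, 0.984, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0]
```

Four modes capture 95% of the reading-level shape variance; resubstitution
accuracy of the SVM rises while informative modes are added and plateaus at
1.0 from M = 5, and the averaged-index rule selects that plateau onset as
the operating point.

The evaluation module reproduces the study's reporting conventions.  Feeding
the published confusion counts (bundled as package data) through it:

```python
from hippomorph.evaluation import (load_reference_counts,
                                   counts_from_row, overall_metrics)
counts = load_reference_counts()
row = counts[(counts.side == "left") & (counts.modes == 3)].iloc[0]
print(overall_metrics(counts_from_row(row)))
# {'percent_correct': 95.238..., 'kappa': 0.90469..., 'mae': 0.047619...,
#  'rmse': 0.21821..., 'rae': 9.545..., 'rrse': 43.69...}
```

The same stages are scriptable from the shell:

```sh
hippomorph simulate --seed 1 -o cohort.json --truth truth.csv
hippomorph sweep -c cohort.json -o metrics.csv
hippomorph report --metrics metrics.csv
# left: optimum M = 5 (accuracy 1.000, resubstitution)
# right: optimum M = 5 (accuracy 1.000, resubstitution)
```

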