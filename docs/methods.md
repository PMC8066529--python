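# Methods

`tracerfuse` quantifies how the fusion of bio-tracers — stable-isotope δ
values and fatty-acid percentages measured on the same individuals —
improves geographic provenance assignment, and ties that improvement to the
geometry of the region-conditional point clouds. This note documents the
models, the synthetic cohort the test-bed runs on, the numerical choices,
and the limits of what the tests show.

## Data model and preprocessing

A cohort is a samples × tracers matrix with one region label per sample
(`BioTracerTable`). Preprocessing follows standard chemometric practice:

- **Fatty-acid percent composition.** Per-sample fatty-acid weights (μg/g)
  are normalised so each sample's fatty acids sum to 100%.
- **Prevalence filter.** A fatty acid is kept if its *mean* percentage across
  samples strictly exceeds 1%. "Presence above 1%" is a typical-abundance
  notion; the mean is stable under single outliers, and the statistic
  (`mean`/`min`/`any`) and threshold are both arguments.
- **Centering and scaling.** Every tracer is z-scored (n−1 denominator) over
  the *whole* table before any inference. Whole-table scaling leaks a small
  amount of test-set information into training; it is nonetheless the
  default because it matches how such datasets are conventionally prepared
  in this literature. A leakage-free protocol (scale on the training split
  only) can be had by scaling splits manually; the split engine itself never
  re-scales.
- **PCA.** A full-rank orthonormal rotation (scikit-learn's SVD-based PCA);
  derived axes are ordered by explained variance and are exactly
  uncorrelated in-sample.

## Classifiers

All three expose per-class posterior probabilities under a uniform prior
(no prior expectation about a sample's origin), so the split engine is
method-agnostic.

- **LDA** — Gaussian classes with a shared pooled covariance
  (scikit-learn's `LinearDiscriminantAnalysis`, uniform priors, SVD solver
  so collinear tracer subsets degrade gracefully instead of failing).
- **NBC** — authored in-package: per class and tracer, a univariate
  Gaussian-kernel density estimate with the classic rule-of-thumb bandwidth
  `0.9 · min(sd, IQR/1.34) · n^(−1/5)`. The class log-likelihood is the sum
  of per-tracer log-densities (conditional independence). Each per-tracer
  density is floored at 1e-300 before the log, so a test point outside every
  class's support returns the uniform posterior rather than NaN; all
  normalisation happens in log space. A within-class constant tracer falls
  back to a minimum bandwidth of 1e-3 (logged).
- **MLP** — two dense layers: a tanh hidden layer of width 32 and a softmax
  output, trained with cross-entropy and full-batch Adam (lr 0.01, 200
  epochs by default, Glorot-style seeded init). Training data are augmented
  by repeating each row `repeats` times and adding centred Gaussian noise of
  s.d. `sigma` to the (already z-scored) tracer values; the default
  `(1000, 0.01)` is the data-hungry setting, while sweep code passes reduced
  values. The network is deliberately implemented in numpy: the sweep engine
  performs tens of thousands of fits on ~60-row training sets, and a
  full-batch tiny net with exact seeding is both faster and more
  reproducible at that scale than a general-purpose minibatch estimator. A
  unit test cross-checks it against scikit-learn's `MLPClassifier` on a toy
  problem. Hidden width, epochs, learning rate and augmentation are all
  arguments; posterior calibration and architecture search are out of scope.

## Split protocol and sweeps

Each replicate draws a stratified split — by default 20 training and 10
test samples per region — fits the classifier on a tracer subset, and
scores the held-out samples. Confusion counts are **pooled** across splits
before row-normalising (stable at small test sets); per-split overall
performance is retained alongside for standard errors, which is the
mean-of-splits variant of the aggregation. Performance is the diagonal of
the row-normalised confusion matrix; overall performance is the unweighted
mean of the diagonal. Ties in the posterior argmax resolve to the first
region in fixed order.

- **Combination sweep.** For each subset size p, all C(d,p) subsets when
  that is at most `max_combos` (default 500), otherwise `max_combos`
  distinct subsets drawn uniformly without replacement via a seeded shuffle
  of the enumerated combinations.
- **Noise sweep.** I.i.d. Gaussian noise of s.d. σ is added to every
  training value before fitting; the test set is untouched. The default grid
  is 9 log-spaced points spanning 1e-4 to 10 (endpoints fixed, interior
  points a package choice).
- **PCA sweep.** The first k derived axes form the tracer set; the rotation
  is fitted once on the whole scaled table.
- **Multi-sample fusion.** k same-region test samples are combined by
  summing log-posteriors (the independence product rule) and taking the
  argmax; majority voting is available behind `fusion_rule="vote"`. The
  product rule is the default because it is the Bayes-consistent combination
  for independent samples and meshes with the NBC's own framing. Within a
  split, each region's test samples are shuffled and partitioned into
  ⌊n_test/k⌋ disjoint groups; the remainder is dropped.
- **Training-size sweep.** The split spec's training count varies over a
  grid with the test count held fixed.

A failed split (e.g. a singular fit on a degenerate subset) is logged and
skipped, and the failure count is reported in the summary.

## Geometry diagnostics

- **Between-region variance fraction.** `Σ_r n_r‖x̄_r − x̄‖² / Σ_i‖x_i − x̄‖²`
  on the subset columns — the one-way ANOVA between/total ratio; between-
  and within-fractions sum to one by construction.
- **Centroid distances.** Euclidean distances between per-region means.
- **Hull overlap.** Per region, the ⌈0.9·n⌉ points closest to their own
  centroid are retained (ceiling rule; 27 of 30 at the default cohort size)
  to trim outliers; convex hulls are built in 2-D or 3-D, and the overlap is
  the sum of the **pairwise** intersection measures divided by the sum of
  the hull measures. Where all three hulls share a region, the pairwise sum
  counts it three times; an inclusion–exclusion variant
  (`triple_rule="inclusion-exclusion"`, 2-D) subtracts twice the triple
  intersection so the union overlap is counted once. The literal pairwise
  sum is the default because it is the plainly-stated quantity; the variant
  exists because the pairwise sum can exceed what a fraction-of-union
  reading would give (it reaches 1.0 for three coincident hulls, versus 1/3
  under inclusion–exclusion). 2-D intersections use shapely polygon
  clipping; 3-D intersections stack both hulls' facet inequalities, find a
  Chebyshev-centre interior point by linear programming, and run a halfspace
  intersection (empty or degenerate systems return volume 0). Both routes
  are validated against an independent Monte-Carlo rejection oracle
  (uniform points in the joint bounding box, membership via facet
  inequalities). Hulls in more than 3 dimensions are out of scope.
- **Performance–geometry regression.** Nonlinear least squares of
  performance y against a metric x with the bounded, monotone saturating
  form `y = c + (a − c)(1 − exp(−b·x))`, b ≥ 0 and the intercept c floored
  at chance (1/R) when requested. The functional form is this package's
  reconstruction — any bounded saturating family would serve — so R² values
  are comparable only approximately across analyses. A constant response is
  reported as a degenerate fit with R² = 0 by convention.

## Synthetic cohort and the Bayes oracle

The generator emulates a three-region, 30-per-region, 17-tracer provenance
cohort. Each region is a multivariate Gaussian: means drawn once per preset
from N(0, s²) per tracer under a fixed preset seed (so the preset's
geometry is a property of the preset, while the sampling seed only moves
individuals), unit variances, and exchangeable within-region correlation
ρ = 0.3 representing the spatial covariance among tracers. The separation
s = 0.55 was chosen, using the package's own Bayes-accuracy oracle during
preset design, so that fitted classifiers at 20 training samples per region
score near 0.45 with one tracer and near 0.9 with all 17 — the regime of a
well-separated three-fishery cohort. Optional per-tracer sinh-arcsinh tilts
produce skewed marginals (re-standardised by Gauss–Hermite moments so mean
and variance are preserved) to exercise the KDE classifier beyond
Gaussianity; closed-form densities for tilted tracers require a diagonal
covariance.

Because the generating densities are known, the Bayes-optimal assignment
accuracy is computable: exactly in one Gaussian dimension (dense-grid
integration of the winning density), by Monte Carlo otherwise (true-density
Bayes rule on fresh draws, with a binomial standard error). This ceiling is
what fitted classifiers are compared against, and what the monotonicity
audit evaluates: for random orderings of conditionally independent tracers,
Bayes accuracy along growing prefixes never decreases beyond Monte-Carlo
error. With strongly correlated (redundant) tracers the gain collapses
toward zero — fusion helps through complementary, not repeated,
information. The audit verifies the statement numerically at the
infinite-data limit plus a finite-sample echo with the fitted NBC; it does
not reproduce a symbolic proof.

What the synthetic cohort does *not* emulate: measurement batch effects,
temporal drift of regional fingerprints, heavy-tailed contamination, or the
compositional closure of fatty-acid percentages (tracers enter as
unconstrained reals). Passing tests therefore demonstrate correctness of
the machinery and the qualitative fusion phenomenology, not performance on
any particular real cohort.

## Problem sizes and determinism

Exhaustive settings (500 subsets × 200 splits per subset size) are the
defaults of the sweep API. The test suite and the acceptance script run
reduced designs — typically 15–50 subsets × 25–100 splits, MLP at
augmentation (20, 0.01) and 50–80 epochs — chosen as the smallest sizes at
which the monotonicity and robustness effects are resolved against their
Monte-Carlo standard errors. Every stochastic function takes an explicit
seed; a pipeline run writes a manifest (package version, config hash,
seeds, per-stage row counts) from which re-running reproduces outputs
bit-wise.

## Known limitations

- Whole-table scaling and whole-table PCA leak test information by design
  fidelity; both are documented above and avoidable by splitting first.
- Fitted-classifier performance is not exactly monotone in nested feature
  sets at finite n (pooled-covariance noise can cost ~2–4 points at full
  rank with 60 training samples); the clean monotonicity statement concerns
  the Bayes rule.
- Properties of the synthetic preset are generator-level statements. A
  single 90-sample cohort realization can deviate: because train and test
  splits come from the same fixed table, a lucky draw can push a fitted
  singleton above the generator's single-tracer Bayes ceiling, and a handful
  of tracer pairs can land below their best member. Tests of preset-level
  properties therefore pool over a few cohort replicates.
- The product fusion rule assumes fused samples are independent given the
  region; lots with shared handling histories violate this and will yield
  overconfident fused posteriors.
- Hull overlap is restricted to 2-D/3-D subsets; kernel-density
  hypervolumes are not implemented.
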