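# tracerfuse

Multi-bio-tracer data fusion for geographic provenance assignment.

Food-authentication labs measure **bio-tracers** — stable-isotope δ values
(δ¹⁵N, δ¹³C, δ³⁴S) and fatty-acid percent compositions — on samples of known
origin and ask how reliably a new sample can be assigned back to its region.
`tracerfuse` is a library for the quantitative core of that question: how
does assignment performance grow as tracers are *fused*, how robust is
fusion to measurement noise, and how does performance relate to the geometry
of the region-conditional point clouds?

It is aimed at chemometricians and fisheries/food-provenance researchers who
want a reproducible simulation test-bed around their classifier choices, and
at methodologists studying why horizontal data fusion (combining tracer
classes) works.

## What it computes

Given a region-labelled samples × tracers table (or a synthetic cohort with
known structure), the package provides:

- **Classifiers** behind one posterior contract: LDA (shared-covariance
  Gaussian classes, uniform priors), a kernel-density naive Bayes
  (per-class, per-tracer Gaussian KDEs with the rule-of-thumb bandwidth
  `0.9·min(sd, IQR/1.34)·n^(−1/5)`, joint likelihood by conditional
  independence), and a small two-dense-layer perceptron trained on
  noise-augmented data.
- **Sweep experiments** over repeated stratified splits (default 20
  train / 10 test per region): performance vs number of fused tracers p
  (up to 500 subsets per p), vs training noise σ ∈ [1e-4, 10], vs leading
  PCA axes, vs training-set size, and vs the number k of same-region
  samples fused per decision by the product rule (summed log-posteriors).
  Performance is the diagonal of the row-normalised confusion matrix;
  overall performance is its unweighted mean.
- **Geometry diagnostics**: between-region variance fraction, centroid
  distances, and the convex-hull overlap fraction in 2-D/3-D after
  retaining the 90% of points nearest each region centroid, plus a
  saturating regression `y = c + (a−c)(1−e^{−bx})` of performance on any
  metric.
- A **Bayes-accuracy oracle** for known generators and a numeric audit of
  the statement that fusing conditionally independent tracers never lowers
  Bayes-level naive-Bayes accuracy.

## Worked example

```sh
python examples/02_fusion_sweep.py
```

prints (reduced sweep: 15 subsets × 25 splits per size, seed 42):

```
LDA: p=1:0.473  p=3:0.655  p=5:0.730  p=9:0.833  p=13:0.904  p=17:0.924
NBC: p=1:0.442  p=3:0.600  p=5:0.651  p=9:0.764  p=13:0.855  p=17:0.876
```

Each number is the mean probability of assigning a held-out sample to its
true region when p tracers are fused: a single tracer barely beats chance
(1/3 for three regions), the full 17-tracer panel approaches 0.9. The other
scripts in `examples/` walk through cohort generation and the Bayes ceiling,
noise robustness, multi-sample fusion (three samples at posterior 0.60 fuse
to 0.931), hull-overlap geometry, and the monotonicity audit.

A thin CLI mirrors the library for shell use:

```sh
fuse sweep --method lda --p 1 --p 5 --p 17 --combos 50 --splits 50 --out run/
fuse audit-monotonicity --orderings 20 --n-mc 50000
```

Every run writes a JSON manifest (seeds, config hash, row counts) from which
it can be reproduced bit-wise.

## Loading your own data

`read_table("cohort.csv", region_column="region")` expects a CSV with a
header, one region label column and numeric tracer columns. Fatty-acid
weight tables can be converted with `fa_percent_composition` and filtered
with `prevalence_filter` (keep tracers whose mean share exceeds 1%), then
`center_scale` z-scores everything before inference.

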