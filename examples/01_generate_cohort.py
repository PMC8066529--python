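"""Generate the study-shaped synthetic cohort and inspect its structure.

Three fishing regions, 30 fish each, 17 bio-tracers (3 isotope-like, 14
fatty-acid-like) with exchangeable within-region correlation — the kind of
table a provenance study assembles from lab measurements.
"""

import tracerfuse as tf

spec = tf.sockeye_like(seed=0)
cohort = tf.generate_cohort(spec)
print(f"cohort: {cohort.n_samples} samples × {cohort.n_tracers} tracers")
print(f"regions: {cohort.region_counts()}")

scaled = tf.center_scale(cohort)
print(f"scaled: col means ≈ {scaled.matrix.mean(axis=0).round(12).max()}, "
      f"col sds ≈ {scaled.matrix.std(axis=0, ddof=1).round(6).max()}")

# the Bayes ceiling of the generator: the best any classifier could do
one = tf.bayes_accuracy(spec, subset=[0], n_mc=50_000, seed=1)
full = tf.bayes_accuracy(spec, n_mc=50_000, seed=1)
print(f"Bayes accuracy, 1 tracer : {one.overall:.3f} ± {one.mc_se:.3f}")
print(f"Bayes accuracy, 17 tracers: {full.overall:.3f} ± {full.mc_se:.3f}")
print("-> fusing tracers raises the achievable ceiling from near-chance "
      "(1/3) toward certainty.")
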