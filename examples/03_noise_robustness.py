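"""Fusion buys robustness: many noisy tracers can beat few clean ones.

Gaussian noise is injected into every training value (test data untouched);
because tracers are z-scored, sigma=1 means noise as large as the
within-region spread.
"""

import tracerfuse as tf

table = tf.center_scale(tf.generate_cohort(tf.sockeye_like(seed=0)))

few_clean = tf.noise_sweep(table, "lda", p_values=[5], sigma_grid=[1e-4],
                           max_combos=15, n_splits=25, seed=7)
many_noisy = tf.noise_sweep(table, "lda", p_values=[15], sigma_grid=[1.0],
                            max_combos=15, n_splits=25, seed=7)

a = few_clean["overall"].mean()
b = many_noisy["overall"].mean()
print(f"5 tracers, sigma=1e-4 : {a:.3f}")
print(f"15 tracers, sigma=1.0 : {b:.3f}")
print("-> even with strong training noise, a larger fused panel keeps more "
      "discriminatory power than a small clean one."
      if b > a else "-> (at this reduced problem size the ordering flipped)")
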