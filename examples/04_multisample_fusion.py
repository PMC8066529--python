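"""Fusing several same-lot samples sharpens the provenance call.

If k fish from the same (unknown) region are tested, their per-sample
posteriors combine by the independence product rule — summed log-posteriors.
"""

import numpy as np

import tracerfuse as tf

# the arithmetic first: three samples each giving 0.6 for the true region
fused = tf.fuse_posteriors(np.tile([0.6, 0.2, 0.2], (3, 1)))
print(f"per-sample posterior 0.60 -> fused over k=3: {fused[0]:.3f}")

table = tf.center_scale(tf.generate_cohort(tf.sockeye_like(seed=0)))
ms = tf.multi_sample_performance(table, list(range(9)), "lda",
                                 k_values=[1, 2, 5], n_splits=60, seed=9)
for _, row in ms.iterrows():
    print(f"k={int(row.k_combined)}: overall performance {row.overall:.3f}")
print("-> combining individuals from the same lot raises accuracy without "
      "measuring a single extra tracer.")
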