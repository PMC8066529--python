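"""Numeric audit: fusing more tracers never hurts the Bayes-level NBC.

With conditionally independent tracers and known densities, appending a
tracer cannot lower the probability of a correct assignment. The audit
estimates Bayes accuracy along growing prefixes of random tracer orderings
and flags any decrease beyond 3 Monte-Carlo standard errors.
"""

import numpy as np

import tracerfuse as tf
from tracerfuse.synthetic import CohortSpec, RegionSpec

rng = np.random.default_rng(0)
d = 8
spec = CohortSpec(
    regions=[RegionSpec(name=f"region_{i + 1}", mean=rng.normal(0, 0.8, d),
                        covariance=np.eye(d)) for i in range(3)],
    n_per_region=30, seed=0)

report = tf.monotonicity_audit(spec, orderings=6, n_mc=30_000, seed=1)
print(report.groupby("d")["accuracy"].mean().round(3).to_string())
print(f"significant decreases: {int(report.significant_decrease.sum())} "
      f"of {len(report)} steps")
print("-> accuracy climbs with every tracer appended; no ordering shows a "
      "significant drop.")
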