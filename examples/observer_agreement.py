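"""Bland–Altman agreement between two observers' tongue-temperature
readings from the same thermograms."""

import numpy as np

import tonguefusion as tf

records = tf.generate_cohort(tf.CohortConfig(n_per_group=20, seed=5))
rng = np.random.default_rng(8)
truth = np.array([r.tongue_temp for r in records])
observer_a = truth + rng.normal(0.0, 0.05, truth.size)
observer_b = truth - 0.25 + rng.normal(0.0, 0.05, truth.size)  # reads low

res = tf.bland_altman(observer_a, observer_b)
print(f"mean difference:     {res.mean_difference:+.3f} degC")
print(f"limits of agreement: [{res.lower_loa:+.3f}, {res.upper_loa:+.3f}]")
inside = np.mean((res.differences >= res.lower_loa)
                 & (res.differences <= res.upper_loa))
print(f"differences within limits: {100 * inside:.0f}%")
# The mean difference exposes observer B's systematic -0.25 degC bias; the
# 1.96-SD limits bound where ~95% of per-subject differences fall.
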