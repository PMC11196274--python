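"""Rank all nine wavelet coefficient-combination rules on a handful of
subjects by after-fusion MSE / PSNR."""

import tonguefusion as tf

records = tf.generate_cohort(tf.CohortConfig(n_per_group=3, seed=2))
pairs = [tf.render_tongue_pair(r, seed=40 + i)
         for i, r in enumerate(records)]
aligned = [tf.preprocess_pair(p)[:2] for p in pairs]

best, table = tf.select_best_rule(aligned)
print(table[["mse", "psnr", "ssim", "ncc"]].round(3)
      .sort_values("mse").to_string())
print(f"\nbest rule: {best.name} (minimum mean MSE, ties by maximum PSNR)")
# Rules that average the approximation band keep the fused image near both
# sources (low MSE, high PSNR); extremal approximation operators (max/min)
# push the fused brightness toward one source and pay for it in MSE.
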