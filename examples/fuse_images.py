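"""Fuse one subject's thermal and visible tongue images with the mean-max
wavelet rule and assess the result with full-reference quality metrics."""

import tonguefusion as tf

record = tf.generate_cohort(tf.CohortConfig(n_per_group=1, seed=3))[1]
pair = tf.render_tongue_pair(record, seed=7)
print(f"subject {pair.subject_id} ({record.group}), "
      f"tongue {record.tongue_temp:.2f} degC")
print(f"injected misalignment (dx, dy, theta): "
      f"({pair.true_offset[0]:+.1f} px, {pair.true_offset[1]:+.1f} px, "
      f"{pair.true_offset[2]:+.1f} deg)")

thermal, visible, transform = tf.preprocess_pair(pair)
print(f"recovered registration:                ({transform.dx:+.1f} px, "
      f"{transform.dy:+.1f} px, {transform.theta:+.1f} deg)")

fused = tf.fuse(thermal, visible, "mean-max")
report = tf.quality_report(fused, thermal, visible)
print()
print(report.to_frame().round(3).to_string())
# After fusion, MSE against the sources drops well below the raw
# thermal-vs-visible disparity and SSIM rises — the fused frame carries
# both modalities' content. The registration above should be close to the
# rigid inverse of the injected offset.
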