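"""Simulate the two-group study cohort and compare the groups variable by
variable, the way a screening study reports its Table of demographics."""

import tonguefusion as tf

records = tf.generate_cohort(tf.CohortConfig(n_per_group=80, seed=1))
table = tf.cohort_table(records)

report = tf.group_comparison(
    table.drop(columns=["subject_id", "sex"]), table["group"])
cols = ["normal_mean", "normal_sd", "diabetes_mean", "diabetes_sd",
        "p_value", "label"]
print(report[cols].round(3).to_string())

diff = (report.loc["tongue_temp", "diabetes_mean"]
        - report.loc["tongue_temp", "normal_mean"])
print(f"\nTongue-temperature group difference: {diff:.2f} degC")
# The glycaemic variables (FBG, PPBG, HbA1c) and the tongue temperature
# separate the groups strongly (p < 0.01); anthropometry barely does —
# the same significance pattern the screening setting relies on.
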