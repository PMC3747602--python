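"""Cohort-level statistics: the AGI-vs-age model and group comparison.

Draws a synthetic cohort (21 healthy subjects on a linear age model with
residual scatter, 20 patients offset upward), fits the healthy-group
regression, summarizes Bland-Altman differences from the model and runs
Welch's unequal-variance t-test between the groups.
"""

import sdppg
from sdppg.cohort import (bland_altman_vs_model, compare_groups, fit_agi_age,
                          group_summaries)

subjects = sdppg.generate_cohort(n_healthy=21, n_patient=20,
                                 model=(0.019, -1.556, 0.126),
                                 patient_offset=0.359, seed=17,
                                 build_templates=False)
records = [s.record for s in subjects]

model = fit_agi_age(records, group="healthy")
print(f"healthy-group fit: AGI = {model.slope:.4f} * age "
      f"{model.intercept:+.4f}  (r = {model.r:.3f})")

diffs = bland_altman_vs_model(records, model)
for _, row in group_summaries(diffs).iterrows():
    print(f"  {row['group']:8s} mean diff {row['mean']:+.4f}  "
          f"SD {row['sd']:.4f}  n {int(row['n'])}")

h = diffs.loc[diffs["group"] == "healthy", "diff"]
p = diffs.loc[diffs["group"] == "patient", "diff"]
test = compare_groups(h, p)
print(f"Welch t-test: t = {test.t:.3f}, df = {test.df:.1f}, "
      f"p = {test.p_value:.2e}")
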