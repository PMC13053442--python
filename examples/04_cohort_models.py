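"""Cohort simulation and the mixed-effects group model.

Simulates a 24 + 24 autopsy-style cohort (four muscles, five fields per
muscle, subject-level age/BMI/HbA1c) with an injected diaphragm-specific
group deficit in LVf, then recovers it with the adjusted mixed model and
checks the within-subject muscle hierarchy.
"""

import warnings

from myocap3d.cohortstats import (
    CohortDesign,
    fit_group_model,
    simulate_cohort,
    within_subject_hierarchy,
)

design = CohortDesign(
    muscle_means={"DIA": 20.09, "SC": 13.64, "EXT": 12.57, "VL": 10.13},  # LVf ×10⁻⁴
    group_effects={"DIA": -3.0},  # T2DM deficit confined to the diaphragm
    sd_subject=2.0,
    sd_field=1.0,
)
table = simulate_cohort(design, seed=2)
print(f"cohort: {table.subject.nunique()} subjects, {len(table)} field rows")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    for muscle in ("DIA", "SC", "EXT", "VL"):
        r = fit_group_model(table, "LVf", muscle)
        print(
            f"{muscle:>4}: β = {r.beta:+6.2f}  (95% CI {r.ci_low:+6.2f} … "
            f"{r.ci_high:+6.2f})  p = {r.p:.4f}"
        )
    h = within_subject_hierarchy(table, "LVf")
print("within-subject LVf hierarchy:", h["order"])
# β estimates the adjusted T2DM−CTRL difference per muscle: only the
# diaphragm shows the injected −3.0 deficit; the muscle ranking is preserved.
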