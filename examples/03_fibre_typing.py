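"""Serial-section fibre typing, minimal Feret diameters and IMCL.

Generates three MyHC pseudo-stains (BA-D5, SC-71, 6H1) plus a Sudan-Black
lipid mask with small inter-section misalignment, matches fibres across
sections, calls positivity, classifies types and measures per-fibre IMCL —
then compares everything with the generator's truth table.
"""

import numpy as np

from myocap3d import PhantomSpec, analyse_sections, generate_serial_sections, section_summary

spec = PhantomSpec(seed=4)
type_probs = {"1": 0.40, "1/2a": 0.05, "2a": 0.30, "2a/2x": 0.05, "2x": 0.20}
imcl_means = {"1": 6.0, "1/2a": 5.0, "2a": 4.0, "2a/2x": 3.0, "2x": 2.0}

sections, truth = generate_serial_sections(spec, type_probs, imcl_means)
records = analyse_sections(sections)

truth_types = dict(zip(truth.fibre_id, truth.fibre_type))
correct = sum(1 for r in records if r.fibre_type == truth_types[r.fibre_id])
print(f"typed {correct}/{len(records)} fibres correctly")

summary = section_summary(records, min_fibres=len(records))
print("proportions (%):", {t: round(p, 1) for t, p in summary["proportions_pct"].items()})
print(f"pooled mean minimal Feret: {summary['pooled_mean_diameter']:.1f} µm")
print("IMCL by type (%):", {t: round(v, 2) for t, v in summary["imcl_mean_by_type"].items()})

truth_imcl = dict(zip(truth.fibre_id, truth.imcl_true))
err = [abs(r.imcl_index - truth_imcl[r.fibre_id]) for r in records if np.isfinite(r.imcl_index)]
print(f"max |IMCL measured − truth|: {max(err):.3f} percentage points")
# IMCL is exact at pixel resolution because droplets are measured on the same
# matched fibres the generator painted them into.
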