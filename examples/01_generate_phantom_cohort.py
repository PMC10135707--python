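"""Generate a synthetic pelvis-phantom cohort and inspect its label mechanism.

Builds 120 binary pelvis masks whose surgical-difficulty labels are drawn
from a logistic model of inlet narrowness plus clinical covariates, then
prints the cohort composition and the geometry-label association.
"""

import dataclasses

import numpy as np
from scipy import stats

from pelvistrat.phantom import CohortConfig, generate_cohort, measure_inlet_width

cohort = generate_cohort(dataclasses.replace(CohortConfig(), n_cases=120, seed=7))
m = cohort.manifest

print(f"cases: {len(m)}   difficult fraction: {m.label.mean():.3f} "
      f"(calibrated intercept {cohort.meta['intercept_used']:.2f})")

widths = [measure_inlet_width(c.volume, c.spacing_mm) for c in cohort.cases]
rho, p = stats.spearmanr(widths, m.label)
print(f"measured inlet width vs label: Spearman rho = {rho:.2f} (p = {p:.2e})")
# A strongly negative rho confirms the generative mechanism: narrower inlets
# are labeled difficult more often.

for grp, name in ((1, "difficult"), (0, "non-difficult")):
    g = m[m.label == grp]
    print(f"{name:>13}: male {100 * g.male.mean():.0f}%  BMI {g.bmi.mean():.1f}  "
          f"neoadjuvant {100 * g.neoadjuvant.mean():.0f}%")
# The difficult group should be more male, heavier and more often irradiated,
# mirroring the clinical cohort the generator emulates.
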