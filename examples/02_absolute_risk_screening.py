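"""Score five-year absolute CVD risk and compare eligibility rules.

Treated people are first rolled back to untreated risk-factor levels, scored
with the 1991 Framingham combined-CVD equation, and calibrated so predicted
risk matches the incidence schedules.  Eligibility under the single-risk-
factor guideline synthesis is then compared with a >=5% absolute-risk rule.
"""

import numpy as np

from cvdprevent import (
    ScreeningParameters,
    absolute_risk_eligibility,
    calibrate,
    eligibility_flows,
    five_to_ten_year,
    five_year_risk,
    generate_epi_schedule,
    generate_population,
    load_risk_parameters,
    single_risk_factor_eligibility,
    untreated_profile,
)

pop = generate_population(10_000, seed=1)
sched = generate_epi_schedule()
params = calibrate(pop, sched, load_risk_parameters())

untx = untreated_profile(pop)          # reverse mean drug effects before scoring
risk5 = five_year_risk(untx, params)
print(f"five-year risk: median {100 * np.median(risk5):.1f}%, "
      f"90th pct {100 * np.percentile(risk5, 90):.1f}%")
print(f"rule of thumb: 5% five-year ~ {100 * five_to_ten_year(0.05):.1f}% ten-year risk")

guideline = single_risk_factor_eligibility(untx)
abs5 = absolute_risk_eligibility(
    risk5, ScreeningParameters(bp_threshold=0.05, statin_threshold=0.05)
)
for name, elig in (("guideline synthesis", guideline), (">=5% absolute risk", abs5)):
    any_e = (elig["bp_eligible"] | elig["lipid_eligible"]).mean()
    print(f"{name}: {100 * any_e:.1f}% eligible "
          f"(BP {100 * elig['bp_eligible'].mean():.1f}%, "
          f"lipids {100 * elig['lipid_eligible'].mean():.1f}%)")

# who moves when switching from current treatment to the absolute-risk rule?
current = (pop["on_bp_drugs"] | pop["on_lipid_drugs"]).to_numpy()
flows = eligibility_flows(pop, current, (abs5["bp_eligible"] | abs5["lipid_eligible"]).to_numpy())
print("\nswitching from current use to the >=5% rule (persons):")
for k, v in flows.items():
    print(f"  {k}: {v:,.0f}")
print("The mismatch between current users and rule-eligible people is what")
print("makes the choice of screening rule consequential for costs.")
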