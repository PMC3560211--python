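# Remaining model input parameters (2008 A$ where monetary), with the
# uncertainty specifications used by the probabilistic sensitivity analysis.
# se_scale notes: comorbid relative risks are sampled Normal on lnRR with the
# printed SE mapped to the log scale by the delta method (SE_ln = SE / mean).

disease_costs:
  ihd_first_year: 12921.0        # uniform +/-25% in PSA
  ihd_subsequent: 4539.0
  stroke_first_year: 23581.0
  stroke_subsequent: 3201.0

comorbid_relative_risks:
  stroke_in_ihd:
    male: {mean: 1.32, se: 0.20}
    female: {mean: 1.88, se: 0.30}
  ihd_in_stroke:
    male: {mean: 2.64, se: 0.07}
    female: {mean: 2.85, se: 0.04}

screening:
  gp_participation: {mean: 0.65, se: 0.065}   # Beta in PSA

adherence:
  discontinuation_year1: {mean: 0.40, se: 0.08}  # Beta in PSA

# Aggregate "current practice" annual drug cost lines (actual PBS
# expenditure mix) used for the self-reported-use scenario, and the New
# Zealand statin price comparison (government-only, no patient co-payment).
current_practice_costs:
  lipid: {gov: 559.68, patient: 123.37}
  bp: {gov: 169.59, patient: 47.09}
nz_statin_price: {gov: 18.25, patient: 0.0}

economics:
  discount_rate: 0.03
  wtp_threshold: 50000.0

# Distribution of the number of blood pressure-lowering drugs prescribed
# (1, 2 or at most 3), standing in for the ASAP usage pattern.
bp_drug_count_mix: [0.6, 0.3, 0.1]
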