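"""Probabilistic sensitivity analysis and the cost-effectiveness plane.

Propagates the uncertainty distributions of every input parameter (drug
relative risks, comorbid risks, disease costs, GP participation, drug
discontinuation) through the full pipeline by joint independent sampling,
and summarises the result with 95% uncertainty intervals.
"""

from cvdprevent import (
    ScreeningParameters,
    calibrate,
    generate_epi_schedule,
    generate_population,
    load_risk_parameters,
    run_psa,
    scenario_report,
)

pop = generate_population(4_000, seed=1)
sched = generate_epi_schedule()
params = calibrate(pop, sched, load_risk_parameters())
screening = ScreeningParameters(scenario="absolute_risk",
                                bp_threshold=0.05, statin_threshold=0.10)

res = run_psa(pop, sched, params, screening, n_draws=300, seed=7)
print(scenario_report([res]).to_string(index=False))
print(f"\nexcluded draws: {res.n_excluded}/{res.n_draws}")
lo, hi = res.ui95["icer"]
print(f"ICER 95% uncertainty interval: ${lo:,.0f} to ${hi:,.0f} per QALY")

below = sum(1 for p in res.ce_points
            if p.delta_qaly > 0 and p.delta_cost / p.delta_qaly <= 50_000)
print(f"{100 * below / len(res.ce_points):.0f}% of PSA draws fall below the "
      "$50,000/QALY willingness-to-pay line,")
print("i.e. the probability the scenario is cost-effective at that threshold.")
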