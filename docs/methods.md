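# Methods

This note documents the model implemented in `cvdprevent`: its structure,
assumptions, parameter defaults, numerical conventions, and the design
choices made where the design was genuinely open. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Scope and comparator structure

The package evaluates primary prevention of ischaemic heart disease (IHD)
and stroke with blood-pressure-lowering drugs and statins in a closed cohort
of adults aged 35–84 with no CVD history, followed in annual cycles until
death or age 100. Three intervention scenarios — actual current practice
(self-reported drug use), a synthesis of single-risk-factor guideline
criteria, and absolute-risk screening — are each compared against the same
counterfactual of **no preventive drug intervention**. Because observed
incidence already reflects prevailing drug use, comparator incidence is
back-calculated: baseline = observed / (c·RR + (1 − c)) per age band, sex
and disease, where c is the current-use coverage in the synthetic survey and
RR the pooled effect of the current treatment mix. Scenario and comparator
then run on the same baseline, so a scenario's deltas isolate its own
screening/treatment policy. Differences in government cost between a
scenario and current practice measure potential prescribing savings.

## Five-year absolute risk

Risk scoring uses the 1991 Framingham combined-CVD equation in Weibull
accelerated-failure-time form: μ is linear in sex, ln age, ln systolic BP,
smoking, ln(total:HDL cholesterol), and diabetes (with female interactions);
σ = exp(0.6536 − 0.2402 μ); p₅ = 1 − exp(−exp((ln 5 − μ)/σ)). The
coefficients ship as a CSV data file that is the single source of truth
(checksum-guarded in the tests); left-ventricular hypertrophy, a covariate
of the original equation with no counterpart in the survey fields, defaults
to absent.

Participants reporting current drug use are scored at estimated *untreated*
levels by reversing mean treatment effects: +9.1/+5.5 mmHg systolic/
diastolic; lipids divided by (1 − 0.171) for total cholesterol, (1 + 0.033)
for HDL, (1 − 0.093) for triglycerides.

**Calibration.** Predicted risk is multiplied by one factor per age-band ×
sex cell chosen so the weighted cell-mean calibrated risk equals the
schedule-implied five-year first-event probability 1 − exp(−5(λ_IHD +
λ_stroke)) averaged over cell members. This is the simplest scheme
consistent with matching predicted to observed incidence; a baseline-
survival shift would be an alternative but is not implemented. The operation
is idempotent, and risks are clipped to [1e-9, 1 − 1e-9] to protect
downstream logs. The ten-year conversion p₁₀ = 1 − (1 − p₅)² is the
constant-hazard two-period extension (5% → 9.75% ≈ 10%; 10% → 19% ≈ 20%).

## Screening and eligibility

Screening reach is deterministic cohort accounting — each record's weight is
multiplied by GP attendance (age-band × sex table) × GP participation in
risk assessment (mean 0.65) — rather than per-record random draws;
uncertainty in these fractions is handled by the PSA. Choices made where
the criteria needed operationalising:

* "Blood pressure > 140/90 mmHg" is read as SBP > 140 **or** DBP > 90
  (standard hypertension-guideline semantics), isolated in one predicate.
* "Post-menopausal women < 75 years" is operationalised as female,
  50 ≤ age < 75; 50 is the conventional proxy and is configurable.
* Absolute-risk thresholds are inclusive (≥), matching "at least X% risk".
* Current practice bypasses screening entirely: treatment equals the
  self-reported use flags.
* By default, treatment follows the rule being evaluated — currently treated
  people below the threshold stop; a `grandfather` option keeps them
  treated at current-practice costs and pooled effects.
* Screening visits for people found ineligible carry no cost by default
  (risk assessment assumed to occur within routine attendance).

## Treatment

New prescriptions add blood-pressure drugs in the fixed cost-effective order
diuretic → calcium channel blocker → ACE inhibitor (beta-blockers remain in
the drug table for the current-practice mix but are not newly prescribed);
the number of BP drugs (1, 2, at most 3) follows a configurable mix,
default (0.6, 0.3, 0.1) — an illustrative stand-in for observed usage
patterns, chosen once. Statins are added iff lipid-eligible. Multiple drug
effects combine multiplicatively on the relative-risk scale.

Current-practice users get aggregate PBS cost lines and pooled effects: the
BP pooled RR is Σₖ mix(k) · Πⱼ≤ₖ RRⱼ over the prescribing order. Since they
are prevalent (not incident) users, they are charged the ongoing-monitoring
cost pattern in every year rather than the initiation-year pattern.

Adherence: 40% of starters discontinue at twelve months; they incur full
first-year costs and receive full first-year risk reduction, then
contribute nothing (the simplest reading of discontinuation "at 12
months"); the remainder adhere long term. Gender-specific statin efficacy
can be supplied as an RR-override table; the default uses pooled estimates.

## Markov cohort engine

Five states: WELL, IHD, STROKE, IHD_AND_STROKE, DEAD. The four primary
states carry the epidemiology; the combined state is a bookkeeping extension
required because second-event risks are parameterised (RR of stroke in IHD:
men 1.32, women 1.88; RR of IHD in stroke: men 2.64, women 2.85; sampled on
the log scale in the PSA with SE mapped by the delta method SE_ln = SE/mean,
since the printed SEs carry no scale).

Numerical conventions:

* Annual cycles, no half-cycle correction; rewards use start-of-cycle
  occupancy.
* Rates convert to probabilities jointly by the exponential competing-risks
  split: P(leave) = 1 − e^(−ΣH), apportioned h/ΣH per cause. Zero total
  hazard yields the identity row.
* Case fatality (per-event probability, 28-day convention) routes its share
  of incident events to DEAD within the event cycle, so fatal events spend
  no time in the disease state.
* Background mortality applies to every alive state; the combined state has
  no further event transitions.
* Calendar trends multiply incidence and case fatality by (1 + annual
  change)^cycle; the default −2%/year is an illustrative synthetic value.
* Scenario relative risks apply to first events (out of WELL) only;
  post-event management is not part of the primary-prevention intervention.
* Intervention drug/GP costs accrue while a person is in WELL; after a
  first event, care is represented by the disease treatment costs, so
  continuing to charge prevention costs would double count.
* Event-year disease costs are charged to all incident events (fatal
  included — acute care is incurred); subsequent-year costs to prevalent
  disease occupancy. The combined state pays both diseases' subsequent
  costs.
* Cohort entry is 35–84, but members age past 84 during simulation using
  schedule rows extrapolated to 100; cells reaching age 100 are frozen so
  total occupancy is conserved in every cycle.
* Any transition probability outside [0, 1] raises a validity error naming
  the cycle; in the PSA such draws are excluded and counted.

Costs are constant 2008 A$ (no inflation; all scenarios share the base
year); all costs and QALYs are discounted to baseline at 3% (configurable).
QALYs weight alive person-years by an age/sex utility weight and by
(1 − disability weight) of the occupied state, combined multiplicatively
for the IHD+stroke state.

## Probabilistic sensitivity analysis

"Multivariate" is implemented as joint independent sampling of all uncertain
parameters per draw (no correlation structure is specified for the inputs):
drug RRs Normal on lnRR with SE = CI width/(2·1.96); comorbid RRs Normal on
lnRR via the delta method; disease costs Uniform ±25% around the mean; GP
participation and discontinuation Beta, moment-matched from mean and SE.
Each draw re-runs the whole pipeline (risk → eligibility → regimen → Markov
→ costs); population records are fixed across draws so intervals isolate
parameter uncertainty from sampling noise. The point estimate is the
deterministic run at distribution means; 95% uncertainty intervals are
empirical 2.5/97.5 percentiles. Default 2,000 draws, overridable; the
packaged examples and acceptance script use 200–500 draws, which keeps the
empirical percentiles stable for these quantities while running in seconds.

The published beta-blocker confidence intervals do not bracket their means
(an apparent transposition in the source table); the means are used as
printed, a warning is emitted, and the lnRR SE is taken from the absolute
CI width.

ICER classification: Δcost ≤ 0 with ΔQALY ≥ 0 (not both zero) is
*dominant*; Δcost ≥ 0 with ΔQALY ≤ 0 is *dominated*; both zero is
*indifferent*; otherwise the ratio is compared with the $50,000/QALY
threshold. Cheaper-and-equal-health is classified dominant rather than
forcing a division by zero.

## The synthetic data, and what the tests do and do not show

The generators stand in for non-redistributable inputs (an individual-level
risk-factor survey; national hospital/mortality registry rates; published
utility and disability weights). They reproduce the *structural* features
the analysis depends on: multivariate-normal risk factors on (SBP, DBP,
ln TC, ln HDL, ln TG) with positive SBP–cholesterol correlation, truncated
to physiologic ranges; smoking and diabetes prevalence varying with age;
drug use increasing in age and in the individual's own SBP/TC percentile
(imperfect, non-random targeting — without which comparing current practice
to rule-based eligibility would be uninformative, and with a boost for
using both drug classes so a substantial share of users take more than one
drug); incidence, case fatality and mortality exponential in age; utility
declining linearly with age (0.93 at 35, slope −0.0035/yr); disability
weights 0.15 (IHD) and 0.30 (stroke).

They do **not** reproduce any real population's joint risk-factor
distribution, survey design or weights, the true age profile, or measured
Australian incidence levels. Consequently the package's outputs on the
default population demonstrate the *methods* — ordering of scenarios,
accounting identities, uncertainty propagation — not Australian point
estimates; absolute QALY and dollar figures scale with the synthetic
defaults and should be re-derived with real schedules (all generator
parameters and schedules are user-overridable, and schedules round-trip
through a long-format CSV).

## Known limitations

* No chronic excess mortality for event survivors beyond second-event and
  background risks; survival after non-fatal events is optimistic.
* No treatment of recurrent events within a disease state (first and second
  events only), no aspirin, no adverse drug events, no dose titration.
* Prevention costs and effects stop at the first event; real patients often
  continue the same drugs as secondary prevention.
* Closed cohort: nobody enters at 35 after baseline.
* The mixture of treated and untreated people within a Markov cell is
  resolved by splitting cells at construction (adherent / discontinuer /
  untreated), which is exact for the modelled one-step adherence process
  but cannot represent gradual drop-out.
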