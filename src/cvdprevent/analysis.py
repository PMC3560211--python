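"""Scenario orchestration: from survey records to lifetime cost-effectiveness.

For one prevention scenario this module

1. rolls treated participants back to untreated risk-factor levels and scores
   five-year absolute risk with the calibrated equation;
2. decides who is screened and who is eligible (current practice /
   single-risk-factor guideline synthesis / absolute-risk thresholds);
3. assigns drug regimens (splitting BP-eligible weight over the 1/2/3-drug
   prescribing mix) and an adherence class (long-term adherer vs
   twelve-month discontinuer);
4. back-calculates counterfactual no-intervention incidence from observed
   incidence, current drug-use coverage and pooled treatment effects;
5. runs the Markov cohort engine for the comparator (no intervention) and
   the scenario on that shared baseline, and differences the discounted
   results into QALYs gained, intervention costs (government and patient),
   disease treatment costs averted, and an ICER.

The comparator for every scenario is "no preventive drug intervention", so
scenarios are directly comparable with each other, and cost differences
between a scenario and current practice measure potential prescribing
savings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .costs import (
    CostSchedule,
    current_practice_cost,
    intervention_cost,
    load_cost_schedule,
    load_model_params,
)
from .eligibility import (
    ScreeningParameters,
    absolute_risk_eligibility,
    screened_fraction,
    single_risk_factor_eligibility,
)
from .errors import ConfigurationError
from .markov import (
    AGE_MAX,
    AGE_MIN,
    CohortCells,
    CohortTrace,
    ComorbidRisks,
    run_cohort,
)
from .population import SEX_INDEX, EpiSchedule
from .risk import RiskParameters, five_year_risk, untreated_profile
from .treatment import (
    AdherenceModel,
    BP_PRESCRIBING_ORDER,
    Regimen,
    drug_classes_from_table,
    load_drug_table,
    pooled_bp_rr,
    regimen_mix,
)

__all__ = ["ScenarioOutcome", "ModelContext", "run_scenario", "back_calculated_schedule"]

LONG_TERM = 10_000  # treat_years sentinel for long-term adherers


@dataclass
class ModelContext:
    """Shared inputs for scenario runs; PSA swaps parameter values in here."""

    drug_table: pd.DataFrame = field(default_factory=load_drug_table)
    model_params: dict = field(default_factory=load_model_params)
    rr_overrides: dict[str, tuple[float, float]] | None = None
    comorbid: ComorbidRisks | None = None
    adherence: AdherenceModel | None = None
    cost_schedule: CostSchedule | None = None
    nz_statin_price: bool = False
    bp_mix: tuple[float, ...] | None = None
    prescribing_order: tuple[str, ...] = BP_PRESCRIBING_ORDER
    discount_rate: float | None = None

    def __post_init__(self) -> None:
        mp = self.model_params
        if self.comorbid is None:
            cr = mp["comorbid_relative_risks"]
            self.comorbid = ComorbidRisks(
                rr_stroke_in_ihd=(cr["stroke_in_ihd"]["male"]["mean"],
                                  cr["stroke_in_ihd"]["female"]["mean"]),
                rr_ihd_in_stroke=(cr["ihd_in_stroke"]["male"]["mean"],
                                  cr["ihd_in_stroke"]["female"]["mean"]),
            )
        if self.adherence is None:
            self.adherence = AdherenceModel(
                mp["adherence"]["discontinuation_year1"]["mean"]
            )
        if self.cost_schedule is None:
            self.cost_schedule = load_cost_schedule(
                nz_statin_price=self.nz_statin_price,
                params=mp,
                drug_table=self.drug_table,
            )
        if self.bp_mix is None:
            self.bp_mix = tuple(mp["bp_drug_count_mix"])
        if self.discount_rate is None:
            self.discount_rate = mp["economics"]["discount_rate"]
        self.drugs = drug_classes_from_table(self.drug_table, self.rr_overrides)


@dataclass
class ScenarioOutcome:
    """Deterministic lifetime results for one scenario vs no intervention."""

    scenario: str
    qalys_gained: float
    gov_cost: float
    patient_cost: float
    treatment_costs_averted: float     # negative when costs are averted
    icer: float | str
    comparator: str = "no_intervention"
    trace: CohortTrace | None = None
    comparator_trace: CohortTrace | None = None
    eligibility: dict[str, float] = field(default_factory=dict)

    @property
    def net_cost(self) -> float:
        return self.gov_cost + self.patient_cost + self.treatment_costs_averted


def _pattern_rrs(ctx: ModelContext) -> dict[str, tuple[float, float]]:
    """Pooled (rr_ihd, rr_stroke) per current-use pattern."""
    bp_i = pooled_bp_rr("ihd", ctx.bp_mix, ctx.drugs, ctx.prescribing_order)
    bp_s = pooled_bp_rr("stroke", ctx.bp_mix, ctx.drugs, ctx.prescribing_order)
    st = ctx.drugs["statin"]
    return {
        "bp": (bp_i, bp_s),
        "lipid": (st.rr_ihd, st.rr_stroke),
        "both": (bp_i * st.rr_ihd, bp_s * st.rr_stroke),
    }


def back_calculated_schedule(
    population: pd.DataFrame, schedule: EpiSchedule, ctx: ModelContext
) -> EpiSchedule:
    """Counterfactual (no-intervention) incidence schedules.

    Observed incidence reflects the prevailing mix of treated and untreated
    people, so per age band and sex the observed rate is divided by the
    use-share-weighted relative-risk multiplier
    sum_g share_g * rr_g over patterns g in {none, bp, lipid, both}.
    Band shares are extended flat beyond the oldest surveyed band.
    """
    rrs = _pattern_rrs(ctx)
    pop = population
    pattern = np.select(
        [
            pop["on_bp_drugs"] & pop["on_lipid_drugs"],
            pop["on_bp_drugs"],
            pop["on_lipid_drugs"],
        ],
        ["both", "bp", "lipid"],
        default="none",
    )
    bands = np.clip((pop["age"].to_numpy(dtype=int) - 35) // 10, 0, 4)
    w = pop["weight"].to_numpy(dtype=float)
    female = (pop["sex"] == "female").to_numpy()

    mult = {"ihd": np.ones((AGE_MAX - AGE_MIN + 1, 2)),
            "stroke": np.ones((AGE_MAX - AGE_MIN + 1, 2))}
    sched_band = np.clip((schedule.ages - 35) // 10, 0, 4)
    for b in range(5):
        for sx in (0, 1):
            mask = (bands == b) & (female == bool(sx))
            if not mask.any():
                continue
            total = w[mask].sum()
            for disease, di in (("ihd", 0), ("stroke", 1)):
                m = 0.0
                for g in ("none", "bp", "lipid", "both"):
                    share = w[mask & (pattern == g)].sum() / total
                    rr = 1.0 if g == "none" else rrs[g][di]
                    m += share * rr
                mult[disease][sched_band == b, sx] = m

    out = schedule.copy()
    out.incidence_ihd = schedule.incidence_ihd / mult["ihd"]
    out.incidence_stroke = schedule.incidence_stroke / mult["stroke"]
    return out


class _CellBuilder:
    """Accumulates weight into homogeneous (age, sex, regimen, adherence) cells."""

    def __init__(self) -> None:
        self._acc: dict[tuple, float] = {}

    def add(self, age: int, sex_idx: int, weight: float, rr=(1.0, 1.0),
            treat_years: int = 0, cost_y1=(0.0, 0.0), cost_later=(0.0, 0.0)) -> None:
        if weight <= 0:
            return
        key = (int(age), int(sex_idx), float(rr[0]), float(rr[1]), int(treat_years),
               float(cost_y1[0]), float(cost_later[0]),
               float(cost_y1[1]), float(cost_later[1]))
        self._acc[key] = self._acc.get(key, 0.0) + weight

    def build(self) -> CohortCells:
        if not self._acc:
            return CohortCells.untreated(np.array([], dtype=int),
                                         np.array([], dtype=int), np.array([]))
        keys = np.array(list(self._acc.keys()))
        w = np.array(list(self._acc.values()))
        return CohortCells(
            age0=keys[:, 0].astype(int),
            sex_idx=keys[:, 1].astype(int),
            weight=w,
            rr_ihd=keys[:, 2],
            rr_stroke=keys[:, 3],
            treat_years=keys[:, 4].astype(int),
            gov_cost_y1=keys[:, 5],
            gov_cost_later=keys[:, 6],
            patient_cost_y1=keys[:, 7],
            patient_cost_later=keys[:, 8],
        )


def _comparator_cells(population: pd.DataFrame) -> CohortCells:
    grp = population.assign(
        sex_idx=[SEX_INDEX[s] for s in population["sex"]]
    ).groupby(["age", "sex_idx"])["weight"].sum().reset_index()
    return CohortCells.untreated(
        grp["age"].to_numpy(), grp["sex_idx"].to_numpy(), grp["weight"].to_numpy()
    )


def _eligibility_masks(
    population_untreated: pd.DataFrame,
    risk5: np.ndarray,
    screening: ScreeningParameters,
) -> pd.DataFrame:
    if screening.scenario == "current_practice":
        return pd.DataFrame(
            {"bp_eligible": population_untreated["on_bp_drugs"].to_numpy(dtype=bool),
             "lipid_eligible": population_untreated["on_lipid_drugs"].to_numpy(dtype=bool)}
        )
    if screening.scenario == "single_risk_factor":
        return single_risk_factor_eligibility(
            population_untreated, screening.menopause_age
        )
    return absolute_risk_eligibility(risk5, screening)


def scenario_cells(
    population: pd.DataFrame,
    risk5: np.ndarray,
    screening: ScreeningParameters,
    ctx: ModelContext,
) -> tuple[CohortCells, dict[str, float]]:
    """Build simulation cells for an intervention scenario.

    Returns the cells plus summary weight totals (treated persons starting,
    persons screened, eligible persons) used for eligibility-flow reporting.
    """
    elig = _eligibility_masks(population, risk5, screening)
    pop = population
    age = pop["age"].to_numpy(dtype=int)
    sex = pop["sex"].to_numpy()
    sex_idx = np.array([SEX_INDEX[s] for s in sex])
    w = pop["weight"].to_numpy(dtype=float)
    d = ctx.adherence.discontinuation_year1
    cs = ctx.cost_schedule

    if screening.scenario == "current_practice":
        s_frac = np.ones(len(pop))
    else:
        s_frac = screened_fraction(age, sex, screening)

    bp_e = elig["bp_eligible"].to_numpy(dtype=bool)
    lip_e = elig["lipid_eligible"].to_numpy(dtype=bool)
    any_e = bp_e | lip_e

    builder = _CellBuilder()
    info = {
        "screened": float((w * s_frac).sum()),
        "eligible": float(w[any_e].sum()),
        "treated_start": 0.0,
    }

    keyframe = pd.DataFrame(
        {"age": age, "sex_idx": sex_idx, "bp": bp_e, "lip": lip_e,
         "s": s_frac, "w": w}
    )

    if screening.scenario == "current_practice":
        rrs = _pattern_rrs(ctx)
        pattern = np.select([bp_e & lip_e, bp_e, lip_e], ["both", "bp", "lipid"],
                            default="none")
        keyframe["pattern"] = pattern
        for (a, sx, pat), grp in keyframe.groupby(["age", "sex_idx", "pattern"]):
            wt = grp["w"].sum()
            if pat == "none":
                builder.add(a, sx, wt)
                continue
            # prevalent users: ongoing-monitoring costs in every year
            cost = current_practice_cost(pat, "later", cs)
            builder.add(
                a, sx, wt, rr=rrs[pat], treat_years=LONG_TERM,
                cost_y1=(cost.gov, cost.patient),
                cost_later=(cost.gov, cost.patient),
            )
            info["treated_start"] += wt
        return builder.build(), info

    grandfathered = (
        (pop["on_bp_drugs"] | pop["on_lipid_drugs"]).to_numpy(dtype=bool) & ~any_e
        if screening.grandfather
        else np.zeros(len(pop), dtype=bool)
    )
    keyframe["gf"] = grandfathered
    rrs_cp = _pattern_rrs(ctx) if screening.grandfather else None

    for (a, sx, bpe, lpe, gf), grp in keyframe.groupby(
        ["age", "sex_idx", "bp", "lip", "gf"]
    ):
        wt = grp["w"].sum()
        s = float(grp["s"].iloc[0])
        if gf:
            pat_mask = grp.index
            pat = np.select(
                [pop.loc[pat_mask, "on_bp_drugs"] & pop.loc[pat_mask, "on_lipid_drugs"],
                 pop.loc[pat_mask, "on_bp_drugs"]],
                ["both", "bp"], default="lipid",
            )
            for p_name in ("both", "bp", "lipid"):
                wt_p = grp.loc[pat == p_name, "w"].sum()
                if wt_p <= 0:
                    continue
                cost = current_practice_cost(p_name, "later", cs)
                builder.add(a, sx, wt_p, rr=rrs_cp[p_name], treat_years=LONG_TERM,
                            cost_y1=(cost.gov, cost.patient),
                            cost_later=(cost.gov, cost.patient))
                info["treated_start"] += wt_p
            continue
        if not (bpe or lpe):
            builder.add(a, sx, wt)
            continue
        # unscreened share stays untreated
        builder.add(a, sx, wt * (1.0 - s))
        info["treated_start"] += wt * s
        for regimen, prob in regimen_mix(bpe, lpe, ctx.bp_mix, ctx.drugs,
                                         ctx.prescribing_order):
            rr = (
                _combined(regimen, "ihd"),
                _combined(regimen, "stroke"),
            )
            c1 = intervention_cost(regimen, 1, cs)
            cl = intervention_cost(regimen, "later", cs)
            wt_r = wt * s * prob
            # twelve-month discontinuers: year-1 effect and cost only
            builder.add(a, sx, wt_r * d, rr=rr, treat_years=1,
                        cost_y1=(c1.gov, c1.patient), cost_later=(0.0, 0.0))
            builder.add(a, sx, wt_r * (1.0 - d), rr=rr, treat_years=LONG_TERM,
                        cost_y1=(c1.gov, c1.patient), cost_later=(cl.gov, cl.patient))
    return builder.build(), info


def _combined(regimen: Regimen, disease: str) -> float:
    from .treatment import combined_rr

    return combined_rr(regimen, disease)


def run_scenario(
    population: pd.DataFrame,
    schedule: EpiSchedule,
    risk_params: RiskParameters,
    screening: ScreeningParameters,
    ctx: ModelContext | None = None,
    keep_traces: bool = False,
) -> ScenarioOutcome:
    """Deterministic lifetime evaluation of one scenario vs no intervention."""
    ctx = ctx or ModelContext()
    pop_untx = untreated_profile(population)
    risk5 = five_year_risk(pop_untx, risk_params)

    baseline = back_calculated_schedule(population, schedule, ctx)
    comp_cells = _comparator_cells(population)
    comp_trace = run_cohort(comp_cells, baseline, ctx.cost_schedule,
                            ctx.comorbid, ctx.discount_rate)

    cells, info = scenario_cells(pop_untx, risk5, screening, ctx)
    if float(cells.weight.sum() if len(cells) else 0.0) > 0:
        scen_trace = run_cohort(cells, baseline, ctx.cost_schedule,
                                ctx.comorbid, ctx.discount_rate)
    else:
        scen_trace = comp_trace

    dq = scen_trace.total_qalys - comp_trace.total_qalys
    averted = scen_trace.total_disease_cost - comp_trace.total_disease_cost
    gov = scen_trace.total_gov_cost
    pat = scen_trace.total_patient_cost
    from .psa import icer as _icer

    icer_val = _icer(gov + pat + averted, dq,
                     ctx.model_params["economics"]["wtp_threshold"])
    return ScenarioOutcome(
        scenario=screening.scenario,
        qalys_gained=dq,
        gov_cost=gov,
        patient_cost=pat,
        treatment_costs_averted=averted,
        icer=icer_val.ratio if icer_val.classification == "ratio"
        else icer_val.classification,
        trace=scen_trace if keep_traces else None,
        comparator_trace=comp_trace if keep_traces else None,
        eligibility=info,
    )
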