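"""Discrete-time Markov cohort model of ischaemic heart disease and stroke.

States: WELL, IHD, STROKE, IHD_AND_STROKE, DEAD.  The four primary states
(WELL, IHD, STROKE, DEAD) carry the epidemiology; the combined state is a
bookkeeping extension needed because second-event risks are parameterised
(sex-specific relative risks of stroke given IHD and of IHD given stroke).

Annual cycles run from the 2008 baseline until everyone is dead or aged 100,
with no half-cycle correction.  Per cycle and stratum, cause-specific rates
are converted jointly to probabilities with the exponential competing-risks
split: with hazards h_1..h_k and H = sum h_j, the probability of leaving the
state is 1 - exp(-H), apportioned h_j / H to each cause.  A share of
incident events equal to the (trended) case fatality is fatal and routes to
DEAD within the event cycle, so fatal events spend no time in the disease
state; background mortality applies to every alive state.  Calendar trends
multiply incidence and case fatality by (1 + annual change)^cycle.

Scenario relative risks act on first events only (transitions out of WELL):
after a first event the person is under disease management, which the model
prices separately, so primary-prevention effects and costs stop there.

Rewards per cycle use start-of-cycle occupancy: quality-adjusted life years
(utility weight by age and sex times one minus the disability weight of the
occupied disease state), intervention costs (WELL occupancy of treated
sub-cohorts), event-year disease costs on incident events (fatal included)
and subsequent-year costs on prevalent disease occupancy.  Everything is
discounted to baseline at 3% per year by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd

from .costs import CostSchedule
from .errors import DomainError, NumericalValidityError
from .population import AGE_MAX, AGE_MIN, SEX_INDEX, EpiSchedule

__all__ = [
    "HealthState",
    "ComorbidRisks",
    "CohortCells",
    "CohortTrace",
    "back_calculate_baseline_incidence",
    "build_transition_matrix",
    "run_cohort",
    "qalys",
    "discount",
]


class HealthState(IntEnum):
    WELL = 0
    IHD = 1
    STROKE = 2
    IHD_AND_STROKE = 3
    DEAD = 4


N_STATES = len(HealthState)


@dataclass(frozen=True)
class ComorbidRisks:
    """Sex-specific second-event relative risks (first element male)."""

    rr_stroke_in_ihd: tuple[float, float] = (1.32, 1.88)
    rr_ihd_in_stroke: tuple[float, float] = (2.64, 2.85)


def back_calculate_baseline_incidence(observed_rate: float, coverage: float,
                                      rr: float) -> float:
    """Counterfactual no-intervention incidence from observed incidence.

    Observed incidence mixes treated (coverage, at rr x baseline) and
    untreated people, so baseline = observed / (coverage*rr + 1 - coverage);
    applying coverage and rr forward recovers the observed rate exactly.
    """
    if not (0.0 <= coverage <= 1.0):
        raise DomainError("coverage must lie in [0, 1]")
    if rr <= 0:
        raise DomainError("relative risk must be positive")
    denom = coverage * rr + (1.0 - coverage)
    if denom <= 0:
        raise DomainError("effective relative risk multiplier must be positive")
    return observed_rate / denom


def _split_competing(hazards: np.ndarray) -> np.ndarray:
    """Probability of each cause firing within one cycle, exponential split.

    ``hazards``: (..., k) non-negative cause-specific rates.  Returns the
    same shape; rows with all-zero hazards return zeros.
    """
    total = hazards.sum(axis=-1, keepdims=True)
    p_any = -np.expm1(-total)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(total > 0, hazards / np.where(total > 0, total, 1.0), 0.0)
    return share * p_any


def _cycle_probs(
    age_idx: np.ndarray,
    sex_idx: np.ndarray,
    cycle: int,
    schedule: EpiSchedule,
    rr_ihd: np.ndarray,
    rr_stroke: np.ndarray,
    comorbid: ComorbidRisks,
):
    """Vectorised per-cell transition ingredients for one cycle.

    Returns dict of arrays (len = n cells): first-event probabilities from
    WELL (p_ihd1, p_stroke1), second-event probabilities (p_stroke2 from IHD,
    p_ihd2 from STROKE), per-state background-death probabilities, and the
    case fatalities (cf_ihd, cf_stroke).
    """
    ti = schedule.trend_incidence
    tc = schedule.trend_case_fatality
    inc_i = schedule.incidence_ihd[age_idx, sex_idx] * (1.0 + ti["ihd"]) ** cycle
    inc_s = schedule.incidence_stroke[age_idx, sex_idx] * (1.0 + ti["stroke"]) ** cycle
    cf_i = np.clip(
        schedule.case_fatality_ihd[age_idx, sex_idx] * (1.0 + tc["ihd"]) ** cycle, 0, 1
    )
    cf_s = np.clip(
        schedule.case_fatality_stroke[age_idx, sex_idx] * (1.0 + tc["stroke"]) ** cycle,
        0, 1,
    )
    mort = schedule.background_mortality[age_idx, sex_idx]
    rr_s_in_i = np.asarray(comorbid.rr_stroke_in_ihd)[sex_idx]
    rr_i_in_s = np.asarray(comorbid.rr_ihd_in_stroke)[sex_idx]

    # WELL: competing first IHD, first stroke, background death
    well = _split_competing(
        np.stack([inc_i * rr_ihd, inc_s * rr_stroke, mort], axis=-1)
    )
    # IHD: competing second event (stroke) and background death
    ihd = _split_competing(np.stack([inc_s * rr_s_in_i, mort], axis=-1))
    # STROKE: competing second event (IHD) and background death
    stroke = _split_competing(np.stack([inc_i * rr_i_in_s, mort], axis=-1))
    # combined state: background death only
    p_mort_only = -np.expm1(-mort)
    return {
        "p_ihd1": well[..., 0], "p_stroke1": well[..., 1], "p_die_well": well[..., 2],
        "p_stroke2": ihd[..., 0], "p_die_ihd": ihd[..., 1],
        "p_ihd2": stroke[..., 0], "p_die_stroke": stroke[..., 1],
        "p_die_both": p_mort_only,
        "cf_ihd": cf_i, "cf_stroke": cf_s,
    }


def build_transition_matrix(
    age: int,
    sex: str,
    cycle: int,
    schedule: EpiSchedule,
    rr_ihd: float = 1.0,
    rr_stroke: float = 1.0,
    comorbid: ComorbidRisks | None = None,
) -> np.ndarray:
    """Row-stochastic 5x5 one-cycle transition matrix for one stratum."""
    comorbid = comorbid or ComorbidRisks()
    age_idx = np.array([min(int(age), AGE_MAX) - AGE_MIN])
    if age_idx[0] < 0:
        raise DomainError(f"age {age} below modelled range")
    sex_idx = np.array([SEX_INDEX[sex]])
    p = {k: float(v[0]) for k, v in _cycle_probs(
        age_idx, sex_idx, cycle, schedule,
        np.array([rr_ihd]), np.array([rr_stroke]), comorbid
    ).items()}

    M = np.zeros((N_STATES, N_STATES))
    W, I, S, B, D = HealthState
    M[W, I] = p["p_ihd1"] * (1 - p["cf_ihd"])
    M[W, S] = p["p_stroke1"] * (1 - p["cf_stroke"])
    M[W, D] = (p["p_ihd1"] * p["cf_ihd"] + p["p_stroke1"] * p["cf_stroke"]
               + p["p_die_well"])
    M[W, W] = 1.0 - M[W, I] - M[W, S] - M[W, D]
    M[I, B] = p["p_stroke2"] * (1 - p["cf_stroke"])
    M[I, D] = p["p_stroke2"] * p["cf_stroke"] + p["p_die_ihd"]
    M[I, I] = 1.0 - M[I, B] - M[I, D]
    M[S, B] = p["p_ihd2"] * (1 - p["cf_ihd"])
    M[S, D] = p["p_ihd2"] * p["cf_ihd"] + p["p_die_stroke"]
    M[S, S] = 1.0 - M[S, B] - M[S, D]
    M[B, D] = p["p_die_both"]
    M[B, B] = 1.0 - M[B, D]
    M[D, D] = 1.0
    if (M < -1e-15).any() or (M > 1 + 1e-15).any():
        raise NumericalValidityError(
            f"transition probability outside [0, 1] for age {age}, sex {sex}, "
            f"cycle {cycle}"
        )
    return np.clip(M, 0.0, 1.0)


@dataclass
class CohortCells:
    """Struct-of-arrays cohort: one entry per homogeneous simulation cell.

    A cell shares baseline age, sex, scenario relative risks, an adherence
    class (``treat_years``: 0 untreated, 1 first-year-only discontinuer, or a
    large number for long-term adherers) and annual intervention costs.
    """

    age0: np.ndarray
    sex_idx: np.ndarray
    weight: np.ndarray
    rr_ihd: np.ndarray
    rr_stroke: np.ndarray
    treat_years: np.ndarray
    gov_cost_y1: np.ndarray
    gov_cost_later: np.ndarray
    patient_cost_y1: np.ndarray
    patient_cost_later: np.ndarray

    def __len__(self) -> int:
        return len(self.age0)

    @classmethod
    def untreated(cls, age0, sex_idx, weight) -> "CohortCells":
        n = len(age0)
        z = np.zeros(n)
        return cls(
            age0=np.asarray(age0, dtype=int),
            sex_idx=np.asarray(sex_idx, dtype=int),
            weight=np.asarray(weight, dtype=float),
            rr_ihd=np.ones(n), rr_stroke=np.ones(n),
            treat_years=np.zeros(n, dtype=int),
            gov_cost_y1=z.copy(), gov_cost_later=z.copy(),
            patient_cost_y1=z.copy(), patient_cost_later=z.copy(),
        )


@dataclass
class CohortTrace:
    """Aggregated results of a cohort run.

    ``occupancy`` is persons by cycle x stratum x state where a stratum is a
    (baseline age, sex) pair; conservation holds per cycle.  Monetary and
    QALY series are per-cycle totals, discounted and undiscounted.
    """

    n_cycles: int
    strata: pd.DataFrame                      # age0, sex_idx per stratum row
    occupancy: np.ndarray                     # (n_cycles+1, n_strata, N_STATES)
    events_ihd: np.ndarray                    # incident events per cycle
    events_stroke: np.ndarray
    qalys_per_cycle: np.ndarray               # discounted
    qalys_per_cycle_undiscounted: np.ndarray
    gov_cost_per_cycle: np.ndarray            # discounted intervention cost
    patient_cost_per_cycle: np.ndarray
    disease_cost_per_cycle: np.ndarray        # discounted, government
    gov_cost_undiscounted: np.ndarray = None
    patient_cost_undiscounted: np.ndarray = None
    disease_cost_undiscounted: np.ndarray = None
    discount_rate: float = 0.03

    @property
    def total_qalys(self) -> float:
        return float(self.qalys_per_cycle.sum())

    @property
    def total_gov_cost(self) -> float:
        return float(self.gov_cost_per_cycle.sum())

    @property
    def total_patient_cost(self) -> float:
        return float(self.patient_cost_per_cycle.sum())

    @property
    def total_disease_cost(self) -> float:
        return float(self.disease_cost_per_cycle.sum())

    def occupancy_totals(self) -> np.ndarray:
        """Persons per cycle summed over strata and states (conservation)."""
        return self.occupancy.sum(axis=(1, 2))

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: cycle, age0, sex, state, persons."""
        cycles, n_strata, _ = self.occupancy.shape
        recs = []
        sex_names = np.array(["male", "female"])
        for t in range(cycles):
            df = pd.DataFrame(
                self.occupancy[t], columns=[s.name for s in HealthState]
            )
            df.insert(0, "cycle", t)
            df.insert(1, "age0", self.strata["age0"].to_numpy())
            df.insert(2, "sex", sex_names[self.strata["sex_idx"].to_numpy()])
            recs.append(df)
        return pd.concat(recs, ignore_index=True)


def discount(value, years_from_base: int, rate: float = 0.03):
    """Present value at baseline: value / (1 + rate)^years."""
    if rate <= -1.0:
        raise DomainError("discount rate must exceed -100%")
    return np.asarray(value) / (1.0 + rate) ** years_from_base


def run_cohort(
    cells: CohortCells,
    schedule: EpiSchedule,
    cost_schedule: CostSchedule | None = None,
    comorbid: ComorbidRisks | None = None,
    discount_rate: float = 0.03,
    max_age: int = AGE_MAX,
) -> CohortTrace:
    """Simulate all cells over annual cycles until death or ``max_age``.

    Cells that reach ``max_age`` are frozen (no further transitions or
    rewards), so total occupancy is conserved across every cycle.
    """
    comorbid = comorbid or ComorbidRisks()
    n = len(cells)
    n_cycles = int(max_age - cells.age0.min()) if n else 0

    # stratum bookkeeping: map each cell to its (age0, sex) stratum row
    strata = pd.DataFrame({"age0": cells.age0, "sex_idx": cells.sex_idx})
    strata_unique = strata.drop_duplicates().reset_index(drop=True)
    key = {(a, s): i for i, (a, s) in enumerate(
        zip(strata_unique["age0"], strata_unique["sex_idx"]))}
    cell_stratum = np.array(
        [key[(a, s)] for a, s in zip(cells.age0, cells.sex_idx)], dtype=int
    )
    n_strata = len(strata_unique)

    occ = np.zeros((n, N_STATES))
    occ[:, HealthState.WELL] = cells.weight
    occupancy = np.zeros((n_cycles + 1, n_strata, N_STATES))
    events_ihd = np.zeros(n_cycles)
    events_stroke = np.zeros(n_cycles)
    q_disc = np.zeros(n_cycles)
    q_undisc = np.zeros(n_cycles)
    gov = np.zeros(n_cycles)
    pat = np.zeros(n_cycles)
    dis = np.zeros(n_cycles)
    gov_u = np.zeros(n_cycles)
    pat_u = np.zeros(n_cycles)
    dis_u = np.zeros(n_cycles)

    dw = np.array([
        0.0,
        schedule.disability_weight_ihd,
        schedule.disability_weight_stroke,
        1.0 - (1.0 - schedule.disability_weight_ihd)
        * (1.0 - schedule.disability_weight_stroke),
        0.0,
    ])
    state_mult = 1.0 - dw  # DEAD row unused (zero occupancy reward below)

    W, I, S, B, D = HealthState
    for t in range(n_cycles + 1):
        np.add.at(occupancy[t], cell_stratum, occ)
        if t == n_cycles:
            break
        age = cells.age0 + t
        active = age < max_age
        if not active.any():
            continue
        age_idx = np.minimum(age, AGE_MAX) - AGE_MIN
        df = 1.0 / (1.0 + discount_rate) ** t

        # treatment on/off this cycle (cycle t is treatment year t+1)
        treated_now = (t < cells.treat_years) & active
        rr_i = np.where(treated_now, cells.rr_ihd, 1.0)
        rr_s = np.where(treated_now, cells.rr_stroke, 1.0)
        p = _cycle_probs(age_idx, cells.sex_idx, t, schedule, rr_i, rr_s, comorbid)

        # rewards on start-of-cycle occupancy (frozen cells excluded)
        act = active.astype(float)
        util = schedule.utility_weight[age_idx, cells.sex_idx] * act
        alive = occ[:, :D]
        q = float((alive * (util[:, None] * state_mult[None, :D])).sum())
        q_undisc[t] += q
        q_disc[t] += q * df

        # intervention costs accrue on WELL occupancy of treated cells
        year1 = treated_now & (t == 0)
        later = treated_now & (t > 0)
        gcost = np.where(year1, cells.gov_cost_y1, 0.0) + np.where(
            later, cells.gov_cost_later, 0.0
        )
        pcost = np.where(year1, cells.patient_cost_y1, 0.0) + np.where(
            later, cells.patient_cost_later, 0.0
        )
        g = float((occ[:, W] * gcost).sum())
        pp = float((occ[:, W] * pcost).sum())
        gov_u[t] += g
        pat_u[t] += pp
        gov[t] += g * df
        pat[t] += pp * df

        # transitions (vectorised over cells); frozen cells keep occupancy
        new = occ.copy()
        for k in ("p_ihd1", "p_stroke1", "p_die_well", "p_stroke2", "p_die_ihd",
                  "p_ihd2", "p_die_stroke", "p_die_both", "cf_ihd", "cf_stroke"):
            if ((p[k] < -1e-12) | (p[k] > 1 + 1e-12)).any():
                raise NumericalValidityError(
                    f"probability {k} outside [0, 1] at cycle {t}"
                )
        a = act
        flow_w_i = occ[:, W] * p["p_ihd1"] * a
        flow_w_s = occ[:, W] * p["p_stroke1"] * a
        flow_w_d = occ[:, W] * p["p_die_well"] * a
        flow_i_b = occ[:, I] * p["p_stroke2"] * a
        flow_i_d = occ[:, I] * p["p_die_ihd"] * a
        flow_s_b = occ[:, S] * p["p_ihd2"] * a
        flow_s_d = occ[:, S] * p["p_die_stroke"] * a
        flow_b_d = occ[:, B] * p["p_die_both"] * a

        new[:, W] -= flow_w_i + flow_w_s + flow_w_d
        new[:, I] += flow_w_i * (1 - p["cf_ihd"]) - flow_i_b - flow_i_d
        new[:, S] += flow_w_s * (1 - p["cf_stroke"]) - flow_s_b - flow_s_d
        new[:, B] += flow_i_b * (1 - p["cf_stroke"]) + flow_s_b * (1 - p["cf_ihd"]) \
            - flow_b_d
        new[:, D] += (
            flow_w_d + flow_w_i * p["cf_ihd"] + flow_w_s * p["cf_stroke"]
            + flow_i_d + flow_i_b * p["cf_stroke"]
            + flow_s_d + flow_s_b * p["cf_ihd"] + flow_b_d
        )

        ev_i = float((flow_w_i + flow_s_b).sum())
        ev_s = float((flow_w_s + flow_i_b).sum())
        events_ihd[t] = ev_i
        events_stroke[t] = ev_s

        if cost_schedule is not None:
            # event-year costs on all incident events (fatal included);
            # subsequent-year costs on prevalent start-of-cycle occupancy
            d_cost = (
                ev_i * cost_schedule.ihd_cost_year1
                + ev_s * cost_schedule.stroke_cost_year1
                + float((occ[:, I] * a).sum()) * cost_schedule.ihd_cost_subsequent
                + float((occ[:, S] * a).sum()) * cost_schedule.stroke_cost_subsequent
                + float((occ[:, B] * a).sum())
                * (cost_schedule.ihd_cost_subsequent
                   + cost_schedule.stroke_cost_subsequent)
            )
            dis_u[t] += d_cost
            dis[t] += d_cost * df

        occ = new

    return CohortTrace(
        n_cycles=n_cycles,
        strata=strata_unique,
        occupancy=occupancy,
        events_ihd=events_ihd,
        events_stroke=events_stroke,
        qalys_per_cycle=q_disc,
        qalys_per_cycle_undiscounted=q_undisc,
        gov_cost_per_cycle=gov,
        patient_cost_per_cycle=pat,
        disease_cost_per_cycle=dis,
        gov_cost_undiscounted=gov_u,
        patient_cost_undiscounted=pat_u,
        disease_cost_undiscounted=dis_u,
        discount_rate=discount_rate,
    )


def qalys(trace: CohortTrace, schedule: EpiSchedule,
          discount_rate: float | None = None, max_age: int = AGE_MAX) -> float:
    """Recompute discounted QALYs from the trace's stratified occupancy.

    Per cycle: alive person-years x utility weight at attained age and sex x
    (1 - disability weight of the occupied state), discounted to baseline.
    Disease-free states use the utility weight alone.
    """
    if discount_rate is None:
        discount_rate = trace.discount_rate
    dw = np.array([
        0.0,
        schedule.disability_weight_ihd,
        schedule.disability_weight_stroke,
        1.0 - (1.0 - schedule.disability_weight_ihd)
        * (1.0 - schedule.disability_weight_stroke),
    ])
    age0 = trace.strata["age0"].to_numpy()
    sex_idx = trace.strata["sex_idx"].to_numpy()
    total = 0.0
    for t in range(trace.n_cycles):
        age = age0 + t
        active = age < max_age
        age_idx = np.minimum(age, AGE_MAX) - AGE_MIN
        util = schedule.utility_weight[age_idx, sex_idx] * active
        alive = trace.occupancy[t, :, : HealthState.DEAD]
        q = (alive * util[:, None] * (1.0 - dw)[None, :]).sum()
        total += float(discount(q, t, discount_rate))
    return total
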