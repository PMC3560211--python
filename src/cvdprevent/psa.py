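"""Probabilistic sensitivity analysis, ICERs, and scenario reports.

Input-parameter uncertainty is propagated by joint independent sampling of
every uncertain parameter per draw (relative risks lognormal — Normal on
lnRR with the SE recovered from the 95% CI width; probabilities Beta,
moment-matched from mean and SE; treatment costs Uniform within +/-25% of
the mean), re-running the full pipeline — risk, eligibility, regimen, Markov
cohort, costs — for each draw, and taking empirical 2.5th/97.5th percentiles
as 95% uncertainty intervals.  The point estimate is the deterministic run
at distribution means.

An incremental cost-effectiveness ratio compares a scenario against its
comparator: negative net cost with positive health gain is *dominant*,
positive cost with non-positive gain is *dominated*, otherwise the ratio
delta-cost / delta-QALY is judged against a willingness-to-pay threshold
($50,000 per QALY by default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .analysis import ModelContext, ScenarioOutcome, run_scenario
from .eligibility import ScreeningParameters
from .errors import ConfigurationError, ConsistencyError, NumericalValidityError
from .markov import ComorbidRisks
from .population import EpiSchedule
from .risk import RiskParameters
from .treatment import AdherenceModel, load_drug_table

logger = logging.getLogger(__name__)

__all__ = [
    "UncertainParameter",
    "ICERResult",
    "CEPoint",
    "PSAResult",
    "default_uncertain_parameters",
    "sample_parameters",
    "run_psa",
    "icer",
    "scenario_report",
]

Z95 = 1.959963984540054


@dataclass(frozen=True)
class UncertainParameter:
    """One Table-style uncertain input.

    distribution: 'normal_on_log' (mean + 95% CI or SE on the natural scale),
    'beta' (mean + SE, moment-matched), or 'uniform_pm25' (+/-25% around the
    mean).
    """

    name: str
    distribution: str
    mean: float
    se: float | None = None
    ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.distribution not in ("normal_on_log", "beta", "uniform_pm25"):
            raise ConfigurationError(f"{self.name}: unknown distribution")
        if self.distribution == "beta" and not (0.0 < self.mean < 1.0):
            raise ConfigurationError(f"{self.name}: beta mean must lie in (0, 1)")

    def _log_se(self) -> float:
        cached = getattr(self, "_log_se_cache", None)
        if cached is not None:
            return cached
        value = self._compute_log_se()
        object.__setattr__(self, "_log_se_cache", value)
        return value

    def _compute_log_se(self) -> float:
        if self.ci is not None:
            lo, hi = self.ci
            if lo > self.mean or hi < self.mean:
                warnings.warn(
                    f"{self.name}: 95% CI ({lo}, {hi}) inconsistent with mean "
                    f"{self.mean}; using |CI width| for the lnRR SE",
                    stacklevel=2,
                )
                return abs(np.log(hi) - np.log(lo)) / (2.0 * Z95)
            return (np.log(hi) - np.log(lo)) / (2.0 * Z95)
        if self.se is None:
            return 0.0
        # delta method: SE on the natural scale mapped to the log scale
        return self.se / self.mean

    def sample(self, rng: np.random.Generator, size=None):
        if self.distribution == "normal_on_log":
            s = self._log_se()
            if s == 0.0:
                return np.full(size, self.mean) if size else self.mean
            return np.exp(rng.normal(np.log(self.mean), s, size=size))
        if self.distribution == "beta":
            if not self.se:
                return np.full(size, self.mean) if size else self.mean
            v = self.se**2
            k = self.mean * (1.0 - self.mean) / v - 1.0
            if k <= 0:
                raise ConfigurationError(
                    f"{self.name}: SE {self.se} too large for a beta distribution"
                )
            return rng.beta(self.mean * k, (1.0 - self.mean) * k, size=size)
        lo, hi = self.mean * 0.75, self.mean * 1.25
        if self.mean == 0.0:
            return np.full(size, 0.0) if size else 0.0
        return rng.uniform(lo, hi, size=size)


def default_uncertain_parameters(
    drug_table: pd.DataFrame | None = None, model_params: dict | None = None
) -> list[UncertainParameter]:
    """The packaged uncertainty specification: drug RRs (lognormal from CI),
    comorbid RRs (lognormal from SE), disease costs (uniform +/-25%),
    GP participation and discontinuation (beta)."""
    from .costs import load_model_params

    drug_table = drug_table if drug_table is not None else load_drug_table()
    mp = model_params or load_model_params()
    params: list[UncertainParameter] = []
    for row in drug_table.to_dict("records"):
        for disease in ("ihd", "stroke"):
            params.append(
                UncertainParameter(
                    name=f"rr_{disease}_{row['name']}",
                    distribution="normal_on_log",
                    mean=row[f"rr_{disease}"],
                    ci=(row[f"rr_{disease}_lo"], row[f"rr_{disease}_hi"]),
                )
            )
    cr = mp["comorbid_relative_risks"]
    for which, key in (("stroke_in_ihd", "rr_stroke_in_ihd"),
                       ("ihd_in_stroke", "rr_ihd_in_stroke")):
        for sex in ("male", "female"):
            params.append(
                UncertainParameter(
                    name=f"{key}_{sex}",
                    distribution="normal_on_log",
                    mean=cr[which][sex]["mean"],
                    se=cr[which][sex]["se"],
                )
            )
    for name in ("ihd_first_year", "ihd_subsequent",
                 "stroke_first_year", "stroke_subsequent"):
        params.append(
            UncertainParameter(
                name=f"cost_{name}", distribution="uniform_pm25",
                mean=mp["disease_costs"][name],
            )
        )
    params.append(
        UncertainParameter(
            name="gp_participation", distribution="beta",
            mean=mp["screening"]["gp_participation"]["mean"],
            se=mp["screening"]["gp_participation"]["se"],
        )
    )
    params.append(
        UncertainParameter(
            name="discontinuation_year1", distribution="beta",
            mean=mp["adherence"]["discontinuation_year1"]["mean"],
            se=mp["adherence"]["discontinuation_year1"]["se"],
        )
    )
    return params


def sample_parameters(
    params: list[UncertainParameter], seed: int | np.random.Generator
) -> dict[str, float]:
    """One joint independent draw of all parameters; seeded and reproducible."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return {p.name: float(p.sample(rng)) for p in params}


@dataclass(frozen=True)
class ICERResult:
    classification: str          # 'ratio', 'dominant', 'dominated', 'indifferent'
    ratio: float | None
    cost_effective: bool
    threshold: float


def icer(delta_cost: float, delta_qaly: float, threshold: float = 50_000.0) -> ICERResult:
    """Classify and compute an incremental cost-effectiveness ratio."""
    if delta_cost == 0.0 and delta_qaly == 0.0:
        return ICERResult("indifferent", None, False, threshold)
    if delta_qaly >= 0 and delta_cost <= 0:
        # cheaper and no worse (or equal cost and better): dominant
        return ICERResult("dominant", None, True, threshold)
    if delta_qaly <= 0 and delta_cost >= 0:
        return ICERResult("dominated", None, False, threshold)
    ratio = delta_cost / delta_qaly
    return ICERResult("ratio", ratio, bool(ratio <= threshold and delta_qaly > 0),
                      threshold)


@dataclass(frozen=True)
class CEPoint:
    """One PSA draw on the cost-effectiveness plane."""

    delta_cost: float
    delta_qaly: float


QUANTITIES = ("qalys_gained", "gov_cost", "patient_cost",
              "treatment_costs_averted", "net_cost")


@dataclass
class PSAResult:
    """Point estimate with empirical 95% uncertainty intervals and CE cloud."""

    scenario: str
    point: ScenarioOutcome
    ui95: dict[str, tuple[float, float]]
    ce_points: list[CEPoint]
    draws: pd.DataFrame
    n_draws: int
    n_excluded: int
    comparator: str = "no_intervention"

    @property
    def icer_ui95(self) -> tuple[float, float]:
        return self.ui95.get("icer", (np.nan, np.nan))


def _context_for_draw(draw: dict[str, float], base: ModelContext) -> ModelContext:
    rr_overrides = {}
    for name in base.drug_table["name"]:
        key_i, key_s = f"rr_ihd_{name}", f"rr_stroke_{name}"
        if key_i in draw or key_s in draw:
            row = base.drug_table.set_index("name").loc[name]
            rr_overrides[name] = (draw.get(key_i, row["rr_ihd"]),
                                  draw.get(key_s, row["rr_stroke"]))
    comorbid = ComorbidRisks(
        rr_stroke_in_ihd=(draw.get("rr_stroke_in_ihd_male",
                                   base.comorbid.rr_stroke_in_ihd[0]),
                          draw.get("rr_stroke_in_ihd_female",
                                   base.comorbid.rr_stroke_in_ihd[1])),
        rr_ihd_in_stroke=(draw.get("rr_ihd_in_stroke_male",
                                   base.comorbid.rr_ihd_in_stroke[0]),
                          draw.get("rr_ihd_in_stroke_female",
                                   base.comorbid.rr_ihd_in_stroke[1])),
    )
    cost_schedule = replace(
        base.cost_schedule,
        ihd_cost_year1=draw.get("cost_ihd_first_year",
                                base.cost_schedule.ihd_cost_year1),
        ihd_cost_subsequent=draw.get("cost_ihd_subsequent",
                                     base.cost_schedule.ihd_cost_subsequent),
        stroke_cost_year1=draw.get("cost_stroke_first_year",
                                   base.cost_schedule.stroke_cost_year1),
        stroke_cost_subsequent=draw.get("cost_stroke_subsequent",
                                        base.cost_schedule.stroke_cost_subsequent),
    )
    adherence = AdherenceModel(
        draw.get("discontinuation_year1", base.adherence.discontinuation_year1)
    )
    return ModelContext(
        drug_table=base.drug_table,
        model_params=base.model_params,
        rr_overrides=rr_overrides or None,
        comorbid=comorbid,
        adherence=adherence,
        cost_schedule=cost_schedule,
        nz_statin_price=base.nz_statin_price,
        bp_mix=base.bp_mix,
        prescribing_order=base.prescribing_order,
        discount_rate=base.discount_rate,
    )


def run_psa(
    population: pd.DataFrame,
    schedule: EpiSchedule,
    risk_params: RiskParameters,
    screening: ScreeningParameters,
    n_draws: int = 2000,
    seed: int = 0,
    ctx: ModelContext | None = None,
    uncertain: list[UncertainParameter] | None = None,
) -> PSAResult:
    """Full-pipeline PSA: each draw re-runs risk -> eligibility -> regimen ->
    Markov -> costs with jointly sampled parameters.  The population records
    are fixed across draws so the intervals isolate parameter uncertainty."""
    if n_draws < 2:
        raise ConfigurationError("n_draws: at least 2 draws required")
    ctx = ctx or ModelContext()
    uncertain = uncertain if uncertain is not None else default_uncertain_parameters(
        ctx.drug_table, ctx.model_params
    )
    point = run_scenario(population, schedule, risk_params, screening, ctx)

    rng = np.random.default_rng(seed)
    rows = []
    ce_points = []
    n_excluded = 0
    for i in range(n_draws):
        draw = sample_parameters(uncertain, rng)
        dctx = _context_for_draw(draw, ctx)
        dscreen = replace(screening,
                          gp_participation=draw.get("gp_participation",
                                                    screening.gp_participation))
        try:
            out = run_scenario(population, schedule, risk_params, dscreen, dctx)
        except NumericalValidityError as exc:
            n_excluded += 1
            logger.warning("PSA draw %d excluded: %s", i, exc)
            continue
        rows.append(
            {
                "qalys_gained": out.qalys_gained,
                "gov_cost": out.gov_cost,
                "patient_cost": out.patient_cost,
                "treatment_costs_averted": out.treatment_costs_averted,
                "net_cost": out.net_cost,
            }
        )
        ce_points.append(CEPoint(delta_cost=out.net_cost, delta_qaly=out.qalys_gained))
    draws = pd.DataFrame(rows)

    ui95: dict[str, tuple[float, float]] = {}
    for q in QUANTITIES:
        lo, hi = np.percentile(draws[q], [2.5, 97.5])
        ui95[q] = (float(lo), float(hi))
    with np.errstate(divide="ignore", invalid="ignore"):
        icers = draws["net_cost"] / draws["qalys_gained"]
    finite = icers[np.isfinite(icers)]
    if len(finite):
        lo, hi = np.percentile(finite, [2.5, 97.5])
        ui95["icer"] = (float(lo), float(hi))
    return PSAResult(
        scenario=screening.scenario,
        point=point,
        ui95=ui95,
        ce_points=ce_points,
        draws=draws,
        n_draws=n_draws,
        n_excluded=n_excluded,
    )


def _fmt_money(x: float) -> str:
    return f"${x:,.0f}"


def scenario_report(results: list[PSAResult]) -> pd.DataFrame:
    """Lifetime costs, health gain and cost-effectiveness, one row per
    scenario, with 95% uncertainty intervals in parentheses."""
    if not results:
        return pd.DataFrame(
            columns=["scenario", "qalys_gained", "gov_cost", "patient_cost",
                     "treatment_costs_averted", "icer"]
        )
    comparators = {r.comparator for r in results}
    if len(comparators) != 1:
        raise ConsistencyError(f"results mix comparators: {sorted(comparators)}")
    rows = []
    for r in results:
        p = r.point

        def cell(value: float, key: str, fmt=_fmt_money) -> str:
            lo, hi = r.ui95.get(key, (np.nan, np.nan))
            return f"{fmt(value)} ({fmt(lo)} to {fmt(hi)})"

        point_icer = icer(p.net_cost, p.qalys_gained)
        icer_txt = (
            cell(point_icer.ratio, "icer")
            if point_icer.classification == "ratio"
            else point_icer.classification
        )
        rows.append(
            {
                "scenario": r.scenario,
                "qalys_gained": cell(p.qalys_gained, "qalys_gained",
                                     fmt=lambda x: f"{x:,.0f}"),
                "gov_cost": cell(p.gov_cost, "gov_cost"),
                "patient_cost": cell(p.patient_cost, "patient_cost"),
                "treatment_costs_averted": cell(p.treatment_costs_averted,
                                                "treatment_costs_averted"),
                "icer": icer_txt,
            }
        )
    return pd.DataFrame(rows)
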