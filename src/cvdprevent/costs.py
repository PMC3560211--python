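"""Intervention and disease treatment costs (constant 2008 A$).

Intervention cost for a treated person-year = annual drug costs plus the GP
visit / blood test pattern matching the treatment combination (lipid only,
BP only, or both) and year (initiation year vs ongoing monitoring), kept
separate for government and patient.  Disease treatment costs are event-year
and subsequent-year amounts for IHD and stroke, attributed to the government
health sector.  Discounting happens downstream in the Markov engine; no
inflation is applied (all scenarios share the 2008 base year).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd
import yaml

from .errors import ConfigurationError, DomainError
from .treatment import Regimen

__all__ = [
    "CostResult",
    "CostSchedule",
    "load_cost_schedule",
    "load_model_params",
    "intervention_cost",
    "disease_cost",
]


@dataclass(frozen=True)
class CostResult:
    gov: float = 0.0
    patient: float = 0.0

    def __post_init__(self) -> None:
        if self.gov < 0 or self.patient < 0:
            raise ConfigurationError("cost components must be non-negative")

    def __add__(self, other: "CostResult") -> "CostResult":
        return CostResult(self.gov + other.gov, self.patient + other.patient)


def load_model_params(path=None) -> dict:
    """Parse the packaged model-parameter YAML (disease costs, comorbid RRs,
    screening/adherence uncertainty, price overrides, economics)."""
    if path is None:
        path = importlib.resources.files("cvdprevent.data") / "model_params.yaml"
    with open(path) as fh:
        return yaml.safe_load(fh)


@dataclass
class CostSchedule:
    """Medical-cost patterns, drug prices, and disease treatment costs.

    ``medical`` maps (pattern, year_key) -> CostResult where pattern is one
    of 'lipid', 'bp', 'both' and year_key is 1 or 'later'.  ``nz_statin_price``
    swaps the statin's annual cost for the New Zealand price (government
    $18.25, no patient co-payment) without touching anything else.
    """

    medical: dict[tuple[str, object], CostResult]
    drug_costs: dict[str, CostResult]
    current_practice: dict[str, CostResult]
    ihd_cost_year1: float
    ihd_cost_subsequent: float
    stroke_cost_year1: float
    stroke_cost_subsequent: float
    nz_statin_price: bool = False
    nz_statin_cost: CostResult = field(default_factory=lambda: CostResult(18.25, 0.0))

    def drug_cost(self, name: str) -> CostResult:
        if name == "statin" and self.nz_statin_price:
            return self.nz_statin_cost
        return self.drug_costs[name]

    def scale_disease_costs(self, factors: dict[str, float]) -> "CostSchedule":
        """Copy with disease costs multiplied (used by the PSA)."""
        from dataclasses import replace

        return replace(
            self,
            ihd_cost_year1=self.ihd_cost_year1 * factors.get("ihd_cost_year1", 1.0),
            ihd_cost_subsequent=self.ihd_cost_subsequent
            * factors.get("ihd_cost_subsequent", 1.0),
            stroke_cost_year1=self.stroke_cost_year1
            * factors.get("stroke_cost_year1", 1.0),
            stroke_cost_subsequent=self.stroke_cost_subsequent
            * factors.get("stroke_cost_subsequent", 1.0),
        )


def load_cost_schedule(nz_statin_price: bool = False, params: dict | None = None,
                       drug_table: pd.DataFrame | None = None) -> CostSchedule:
    """Assemble the cost schedule from the packaged data files."""
    from .treatment import load_drug_table

    params = params or load_model_params()
    if drug_table is None:
        drug_table = load_drug_table()
    med_path = importlib.resources.files("cvdprevent.data") / "medical_costs.csv"
    med = pd.read_csv(med_path, comment="#")
    medical: dict[tuple[str, object], CostResult] = {}
    for pattern, grp in med.groupby("pattern"):
        for year_key, units_col in ((1, "units_year1"), ("later", "units_later")):
            gov = float((grp["unit_price_gov"] * grp[units_col]).sum())
            pat = float((grp["unit_price_patient"] * grp[units_col]).sum())
            medical[(pattern, year_key)] = CostResult(gov, pat)

    drug_costs = {
        row["name"]: CostResult(row["annual_cost_gov"], row["annual_cost_patient"])
        for row in drug_table.to_dict("records")
    }
    cp = params["current_practice_costs"]
    dcost = params["disease_costs"]
    nz = params["nz_statin_price"]
    return CostSchedule(
        medical=medical,
        drug_costs=drug_costs,
        current_practice={
            "lipid": CostResult(cp["lipid"]["gov"], cp["lipid"]["patient"]),
            "bp": CostResult(cp["bp"]["gov"], cp["bp"]["patient"]),
        },
        ihd_cost_year1=dcost["ihd_first_year"],
        ihd_cost_subsequent=dcost["ihd_subsequent"],
        stroke_cost_year1=dcost["stroke_first_year"],
        stroke_cost_subsequent=dcost["stroke_subsequent"],
        nz_statin_price=nz_statin_price,
        nz_statin_cost=CostResult(nz["gov"], nz["patient"]),
    )


def _year_key(year) -> object:
    if year == 1:
        return 1
    if year == "2+" or (isinstance(year, int) and year >= 2) or year == "later":
        return "later"
    raise DomainError(f"year must be 1 or 2+/'later', got {year!r}")


def intervention_cost(regimen: Regimen, year, schedule: CostSchedule) -> CostResult:
    """Drug costs plus the medical-cost pattern for the regimen and year.

    Empty regimen -> zero cost.  ``year`` is 1 or any of 2+, '2+', 'later'.
    """
    if not regimen.drugs:
        return CostResult(0.0, 0.0)
    key = _year_key(year)
    total = schedule.medical[(regimen.pattern, key)]
    for drug in regimen.drugs:
        total = total + schedule.drug_cost(drug.name)
    return total


def current_practice_cost(pattern: str, year, schedule: CostSchedule) -> CostResult:
    """Annual cost for a self-reported current user (aggregate PBS cost lines
    in place of per-class drug prices, plus the usual medical pattern)."""
    if pattern == "":
        return CostResult(0.0, 0.0)
    if pattern not in ("lipid", "bp", "both"):
        raise DomainError(f"unknown treatment pattern {pattern!r}")
    key = _year_key(year)
    total = schedule.medical[(pattern, key)]
    if pattern in ("lipid", "both"):
        total = total + schedule.current_practice["lipid"]
    if pattern in ("bp", "both"):
        total = total + schedule.current_practice["bp"]
    return total


def disease_cost(state: str, years_since_event: int, schedule: CostSchedule) -> CostResult:
    """Government disease treatment cost for a health state.

    Event-year cost in the year of the event (years_since_event == 0),
    subsequent-years cost thereafter; the combined IHD+stroke state sums both
    diseases' applicable costs.  'well' and 'dead' cost nothing.
    """
    if years_since_event < 0:
        raise DomainError("years_since_event must be non-negative")
    state = state.lower()
    if state in ("well", "dead"):
        return CostResult(0.0, 0.0)
    first = years_since_event == 0
    gov = 0.0
    if state in ("ihd", "ihd_and_stroke"):
        gov += schedule.ihd_cost_year1 if first else schedule.ihd_cost_subsequent
    if state in ("stroke", "ihd_and_stroke"):
        gov += schedule.stroke_cost_year1 if first else schedule.stroke_cost_subsequent
    if gov == 0.0 and state not in ("ihd", "stroke", "ihd_and_stroke"):
        raise DomainError(f"unknown health state {state!r}")
    return CostResult(gov, 0.0)
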