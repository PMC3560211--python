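"""Drug regimens, combined treatment effects, and adherence.

Eligible people receive a statin (if lipid-eligible) and one, two or at most
three blood-pressure-lowering drugs (if BP-eligible), prescribed in a fixed
cost-effective order — diuretic, then calcium channel blocker, then ACE
inhibitor (beta-blockers are kept in the drug table for the current-practice
mix but are not part of new prescriptions).  Effects of multiple drugs on
first-event risk combine multiplicatively on the relative-risk scale.

Adherence is a one-step model: a fraction of starters (mean 40%) discontinue
at twelve months — they incur full first-year costs and receive the full
first-year risk reduction, then contribute nothing — and the remainder
adhere long term.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError

__all__ = [
    "DrugClass",
    "Regimen",
    "AdherenceModel",
    "BP_PRESCRIBING_ORDER",
    "load_drug_table",
    "drug_classes_from_table",
    "assign_regimen",
    "regimen_mix",
    "combined_rr",
    "pooled_bp_rr",
    "effective_coverage",
]

BP_DRUG_NAMES = ("diuretic", "calcium_channel_blocker", "ace_inhibitor", "beta_blocker")

#: New prescriptions add BP drugs in this order (most cost-effective first).
BP_PRESCRIBING_ORDER = ("diuretic", "calcium_channel_blocker", "ace_inhibitor")


@dataclass(frozen=True)
class DrugClass:
    name: str
    rr_ihd: float
    rr_stroke: float
    annual_cost_gov: float = 0.0
    annual_cost_patient: float = 0.0

    def __post_init__(self) -> None:
        if self.rr_ihd <= 0 or self.rr_stroke <= 0:
            raise ConfigurationError(f"{self.name}: relative risks must be positive")
        if self.annual_cost_gov < 0 or self.annual_cost_patient < 0:
            raise ConfigurationError(f"{self.name}: costs must be non-negative")

    @property
    def is_bp_drug(self) -> bool:
        return self.name in BP_DRUG_NAMES


@dataclass(frozen=True)
class Regimen:
    """An individual's set of preventive drug classes."""

    drugs: tuple[DrugClass, ...] = ()

    def __post_init__(self) -> None:
        names = [d.name for d in self.drugs]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"regimen has duplicate drug classes: {names}")
        if self.n_bp_drugs > 3:
            raise ConfigurationError("at most three blood-pressure-lowering drugs")

    @property
    def n_bp_drugs(self) -> int:
        return sum(d.is_bp_drug for d in self.drugs)

    @property
    def includes_statin(self) -> bool:
        return any(d.name == "statin" for d in self.drugs)

    @property
    def pattern(self) -> str:
        """Medical-cost pattern: '', 'lipid', 'bp' or 'both'."""
        has_bp = self.n_bp_drugs > 0
        if has_bp and self.includes_statin:
            return "both"
        if self.includes_statin:
            return "lipid"
        if has_bp:
            return "bp"
        return ""


@dataclass(frozen=True)
class AdherenceModel:
    discontinuation_year1: float = 0.40

    def __post_init__(self) -> None:
        if not (0.0 <= self.discontinuation_year1 <= 1.0):
            raise ConfigurationError("discontinuation_year1: not a probability")


def load_drug_table(path=None) -> pd.DataFrame:
    """Drug class table: RR means and 95% CIs per disease plus annual costs."""
    if path is None:
        path = importlib.resources.files("cvdprevent.data") / "drugs.csv"
    df = pd.read_csv(path, comment="#")
    required = {"name", "rr_ihd", "rr_stroke", "annual_cost_gov", "annual_cost_patient"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"drug table missing columns: {sorted(missing)}")
    return df


def drug_classes_from_table(
    table: pd.DataFrame, rr_overrides: dict[str, tuple[float, float]] | None = None
) -> dict[str, DrugClass]:
    """Build DrugClass objects, optionally overriding (rr_ihd, rr_stroke).

    Overrides are how the probabilistic sensitivity analysis injects sampled
    relative risks, and how gender-specific statin efficacy can be supplied.
    """
    out = {}
    for row in table.to_dict("records"):
        rr_i, rr_s = row["rr_ihd"], row["rr_stroke"]
        if rr_overrides and row["name"] in rr_overrides:
            rr_i, rr_s = rr_overrides[row["name"]]
        out[row["name"]] = DrugClass(
            name=row["name"],
            rr_ihd=rr_i,
            rr_stroke=rr_s,
            annual_cost_gov=row["annual_cost_gov"],
            annual_cost_patient=row["annual_cost_patient"],
        )
    return out


def _validate_mix(mix) -> np.ndarray:
    m = np.asarray(mix, dtype=float)
    if m.shape != (3,) or (m < 0).any() or not np.isclose(m.sum(), 1.0, atol=1e-9):
        raise ConfigurationError(
            "bp_drug_count_mix: must be a probability vector over 1, 2 or 3 drugs"
        )
    return m


def assign_regimen(
    bp_eligible: bool,
    lipid_eligible: bool,
    n_bp: int = 1,
    drugs: dict[str, DrugClass] | None = None,
    order: tuple[str, ...] = BP_PRESCRIBING_ORDER,
) -> Regimen:
    """Regimen for one person: ``n_bp`` BP drugs in prescribing order, plus a
    statin iff lipid-eligible.  Ineligible on both counts -> empty regimen."""
    if drugs is None:
        drugs = drug_classes_from_table(load_drug_table())
    if not (0 <= n_bp <= 3):
        raise ConfigurationError("n_bp: number of BP drugs must be 0-3")
    chosen: list[DrugClass] = []
    if bp_eligible:
        chosen.extend(drugs[name] for name in order[:n_bp])
    if lipid_eligible:
        chosen.append(drugs["statin"])
    return Regimen(tuple(chosen))


def regimen_mix(
    bp_eligible: bool,
    lipid_eligible: bool,
    mix,
    drugs: dict[str, DrugClass] | None = None,
    order: tuple[str, ...] = BP_PRESCRIBING_ORDER,
) -> list[tuple[Regimen, float]]:
    """Split eligibility into (regimen, probability) pairs over the BP-drug
    count distribution; non-BP-eligible people get a single deterministic
    regimen."""
    m = _validate_mix(mix)
    if not bp_eligible:
        return [(assign_regimen(False, lipid_eligible, 0, drugs, order), 1.0)]
    return [
        (assign_regimen(True, lipid_eligible, k, drugs, order), float(m[k - 1]))
        for k in (1, 2, 3)
        if m[k - 1] > 0
    ]


def combined_rr(regimen: Regimen, disease: str) -> float:
    """Multiplicative combination of per-drug relative risks (1.0 if empty)."""
    if disease not in ("ihd", "stroke"):
        raise DomainError(f"disease must be 'ihd' or 'stroke', got {disease!r}")
    attr = f"rr_{disease}"
    rr = 1.0
    for d in regimen.drugs:
        rr *= getattr(d, attr)
    return rr


def pooled_bp_rr(
    disease: str,
    mix,
    drugs: dict[str, DrugClass] | None = None,
    order: tuple[str, ...] = BP_PRESCRIBING_ORDER,
) -> float:
    """Expected combined RR of BP treatment over the drug-count mix.

    pooled = sum_k mix[k] * prod_{j<=k} rr_j with drugs taken in prescribing
    order; used for the current-practice scenario where only the fact of BP
    treatment (not the count) is observed.
    """
    m = _validate_mix(mix)
    if drugs is None:
        drugs = drug_classes_from_table(load_drug_table())
    attr = f"rr_{disease}" if disease in ("ihd", "stroke") else None
    if attr is None:
        raise DomainError(f"disease must be 'ihd' or 'stroke', got {disease!r}")
    total = 0.0
    for k in (1, 2, 3):
        rr = 1.0
        for name in order[:k]:
            rr *= getattr(drugs[name], attr)
        total += m[k - 1] * rr
    return total


def effective_coverage(screened: float, adh: AdherenceModel, year: int) -> float:
    """Treated fraction by treatment year: full in year 1, then reduced by
    twelve-month discontinuation; remaining patients adhere long term."""
    if year < 1:
        raise DomainError("year: treatment years are counted from 1")
    if not (0.0 <= screened <= 1.0):
        raise DomainError("screened: not a probability")
    if year == 1:
        return screened
    return screened * (1.0 - adh.discontinuation_year1)
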