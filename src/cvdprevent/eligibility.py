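"""Screening and treatment-eligibility rules.

Three ways of deciding who receives preventive drugs are compared:

1. **current practice** — whoever already reports taking blood-pressure or
   lipid drugs keeps taking them (no screening step);
2. **single risk factor** — the synthesis of existing guideline and
   prescribing-criteria thresholds on blood pressure and lipids;
3. **absolute risk** — everyone whose five-year absolute CVD risk reaches a
   threshold (optionally different thresholds for blood-pressure drugs and
   statins, e.g. BP drugs at >=5% with statins restricted to >=10%).

Screening reach is deterministic cohort accounting: each record's weight is
scaled by the fraction screened (GP attendance x GP participation in risk
assessment), never by per-record random draws; parameter uncertainty in the
screened fraction is the probabilistic sensitivity analysis's job.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError

__all__ = [
    "ScreeningParameters",
    "load_gp_attendance",
    "single_risk_factor_eligibility",
    "absolute_risk_eligibility",
    "screened_fraction",
    "eligibility_flows",
]

SCENARIOS = ("current_practice", "single_risk_factor", "absolute_risk")


def load_gp_attendance(path=None) -> pd.DataFrame:
    """GP attendance probabilities by age band and sex (long CSV)."""
    if path is None:
        path = importlib.resources.files("cvdprevent.data") / "gp_attendance.csv"
    df = pd.read_csv(path, comment="#")
    if ((df["attendance"] < 0) | (df["attendance"] > 1)).any():
        raise ConfigurationError("gp_attendance: attendance values must be probabilities")
    return df


@dataclass
class ScreeningParameters:
    """Scenario choice plus the screening-process probabilities."""

    scenario: str = "absolute_risk"
    gp_attendance: pd.DataFrame | None = None
    gp_participation: float = 0.65
    bp_threshold: float = 0.05       # five-year risk cutoffs
    statin_threshold: float = 0.05
    menopause_age: int = 50          # proxy for "post-menopausal" in the lipid rules
    grandfather: bool = False        # keep current users treated even if ineligible

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ConfigurationError(f"scenario: {self.scenario!r} not one of {SCENARIOS}")
        if not (0.0 <= self.gp_participation <= 1.0):
            raise ConfigurationError("gp_participation: not a probability")
        for name in ("bp_threshold", "statin_threshold"):
            if not (0.0 < getattr(self, name) < 1.0):
                raise ConfigurationError(f"{name}: must lie in (0, 1)")
        if self.gp_attendance is None:
            self.gp_attendance = load_gp_attendance()


def _as_frame(population) -> pd.DataFrame:
    if isinstance(population, pd.Series):
        return population.to_frame().T
    return population


def single_risk_factor_eligibility(population: pd.DataFrame,
                                   menopause_age: int = 50) -> pd.DataFrame:
    """Apply the single-risk-factor guideline synthesis, vectorised.

    Expects untreated-equivalent risk-factor levels.  Blood-pressure
    eligibility: BP > 140/90 mmHg (read as SBP > 140 OR DBP > 90), or
    BP > 130/80 with diabetes.  Lipid eligibility: any of the seven
    total-cholesterol / HDL / triglyceride / diabetes criteria, where
    "hypertension" means BP-eligible and "post-menopausal women < 75 years"
    is operationalised as female with menopause_age <= age < 75.
    Returns a DataFrame with boolean ``bp_eligible``/``lipid_eligible``.
    """
    pop = _as_frame(population)
    sbp = pop["sbp"].to_numpy(dtype=float)
    dbp = pop["dbp"].to_numpy(dtype=float)
    tc = pop["total_chol"].to_numpy(dtype=float)
    hdl = pop["hdl_chol"].to_numpy(dtype=float)
    tg = pop["triglycerides"].to_numpy(dtype=float)
    age = pop["age"].to_numpy(dtype=float)
    diab = pop["diabetes"].to_numpy(dtype=bool)
    male = (pop["sex"] == "male").to_numpy()

    bp_eligible = (sbp > 140) | (dbp > 90) | (diab & ((sbp > 130) | (dbp > 80)))

    age_sex_window = (male & (35 <= age) & (age <= 75)) | (
        ~male & (age >= menopause_age) & (age < 75)
    )
    lipid_eligible = (
        (diab & (age > 60))
        | (diab & (tc > 5.5))
        | ((tc > 6.5) & (hdl < 1.0))
        | ((tc > 6.5) & bp_eligible)
        | ((tc > 5.5) & (hdl < 1.0) & bp_eligible)
        | (((tc > 7.5) | (tg > 4.0)) & age_sex_window)
        | ((tc > 9.0) | (tg > 8.0))
    )
    return pd.DataFrame(
        {"bp_eligible": bp_eligible, "lipid_eligible": lipid_eligible},
        index=pop.index,
    )


def absolute_risk_eligibility(risk5, params: ScreeningParameters) -> pd.DataFrame:
    """Threshold the five-year risk ("at least" semantics, so >= is inclusive)."""
    r = np.atleast_1d(np.asarray(risk5, dtype=float))
    if ((r < 0) | (r > 1)).any():
        raise DomainError("risk5 must lie in [0, 1]")
    return pd.DataFrame(
        {"bp_eligible": r >= params.bp_threshold,
         "lipid_eligible": r >= params.statin_threshold}
    )


def screened_fraction(age, sex, params: ScreeningParameters) -> np.ndarray | float:
    """Fraction of (age, sex) people screened: GP attendance x participation."""
    age_arr = np.atleast_1d(np.asarray(age, dtype=float))
    sex_arr = np.atleast_1d(np.asarray(sex, dtype=object))
    if (age_arr < 35).any():
        raise DomainError("screening is modelled from age 35")
    att = params.gp_attendance
    out = np.empty(len(age_arr))
    for s in ("male", "female"):
        sub = att[att["sex"] == s]
        lo = sub["age_lo"].to_numpy()
        hi = sub["age_hi"].to_numpy()
        vals = sub["attendance"].to_numpy()
        mask = sex_arr == s
        a = age_arr[mask]
        idx = np.clip(np.searchsorted(lo, a, side="right") - 1, 0, len(lo) - 1)
        if (a > hi[-1]).any():
            raise DomainError("age beyond the attendance table's open-ended band")
        out[mask] = vals[idx]
    result = out * params.gp_participation
    return float(result[0]) if np.isscalar(age) else result


def eligibility_flows(
    population: pd.DataFrame,
    old_rule: np.ndarray | pd.Series,
    new_rule: np.ndarray | pd.Series,
) -> dict[str, float]:
    """Weight totals moving between two treatment rules (eligibility flows).

    ``old_rule``/``new_rule`` are per-record booleans (e.g. current treatment
    flags vs eligibility under a proposed rule).  Returns weight sums of
    people treated under both (``already_treated``), newly eligible, and no
    longer eligible.
    """
    w = population["weight"].to_numpy(dtype=float)
    old = np.asarray(old_rule, dtype=bool)
    new = np.asarray(new_rule, dtype=bool)
    if len(old) != len(w) or len(new) != len(w):
        raise ConfigurationError("rule masks must align with the population")
    return {
        "already_treated": float(w[old & new].sum()),
        "newly_eligible": float(w[~old & new].sum()),
        "no_longer_eligible": float(w[old & ~new].sum()),
    }
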