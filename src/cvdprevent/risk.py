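"""Five-year absolute cardiovascular risk: scoring, adjustment, calibration.

The absolute-risk screening arm of the analysis scores every participant with
the 1991 Framingham combined-CVD equation (Weibull accelerated failure time
model on age, sex, systolic blood pressure, the total:HDL cholesterol ratio,
smoking, diabetes and ECG left-ventricular hypertrophy).  The coefficients
live in a data file — ``data/framingham_cvd_1991.csv`` — which is the single
source of truth for the equation; this module only evaluates it.

Because the equation was fitted to a US cohort, predicted risks are
calibrated to the modelled population's own incidence with one multiplicative
factor per age-band x sex cell, chosen so the weighted mean calibrated
five-year risk in each cell equals the five-year first-event probability
implied by the incidence schedules, 1 - exp(-5 (i_ihd + i_stroke)).

Participants already on preventive drugs are scored at their estimated
*untreated* risk-factor levels by reversing mean treatment effects
(9.1/5.5 mmHg blood-pressure reduction; 17.1% TC, 25.6% LDL, 9.3% TG
reductions and 3.3% HDL increase on statins).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import CalibrationError, ConfigurationError, DomainError, ParameterError
from .population import AGE_BANDS, EpiSchedule

__all__ = [
    "TreatmentAdjustment",
    "RiskParameters",
    "load_risk_parameters",
    "untreated_profile",
    "five_year_risk",
    "calibrate",
    "five_to_ten_year",
    "RISK_CLIP",
]

#: Predicted risks are clipped to this open interval to protect downstream logs.
RISK_CLIP = (1e-9, 1.0 - 1e-9)

REQUIRED_TERMS = (
    "intercept",
    "female",
    "ln_age",
    "female_ln_age",
    "ln_sbp",
    "smoker",
    "ln_tc_hdl_ratio",
    "diabetes",
    "female_diabetes",
    "lvh",
    "sigma_const",
    "sigma_mu",
)


@dataclass(frozen=True)
class TreatmentAdjustment:
    """Mean on-treatment effects reversed to recover untreated levels."""

    sbp_reduction: float = 9.1       # mmHg
    dbp_reduction: float = 5.5       # mmHg
    tc_reduction_frac: float = 0.171
    ldl_reduction_frac: float = 0.256
    tg_reduction_frac: float = 0.093
    hdl_increase_frac: float = 0.033

    def __post_init__(self) -> None:
        if self.sbp_reduction <= 0 or self.dbp_reduction <= 0:
            raise ConfigurationError("blood-pressure reductions must be positive mmHg")
        for name in ("tc_reduction_frac", "ldl_reduction_frac",
                     "tg_reduction_frac", "hdl_increase_frac"):
            if not (0.0 < getattr(self, name) < 1.0):
                raise ConfigurationError(f"{name}: must lie in (0, 1)")


@dataclass
class RiskParameters:
    """Risk-equation coefficients plus per-cell calibration scale factors.

    ``calibration`` maps ``(age_band, sex) -> factor`` with factor > 0; an
    uncalibrated parameter set uses factor 1 everywhere.
    """

    coefficients: dict[str, float]
    calibration: dict[tuple[tuple[int, int], str], float] = field(default_factory=dict)
    age_bands: tuple[tuple[int, int], ...] = AGE_BANDS

    def __post_init__(self) -> None:
        missing = [t for t in REQUIRED_TERMS if t not in self.coefficients]
        if missing:
            raise ParameterError(f"risk-equation coefficients missing: {missing}")
        for cell, f in self.calibration.items():
            if not f > 0:
                raise ConfigurationError(f"calibration_factor for {cell}: must be positive")

    def calibration_factor(self, age, sex) -> np.ndarray:
        """Vectorised per-individual factor lookup (1.0 where uncalibrated).

        Ages past the last band reuse the last band's factor (cohort members
        age beyond the survey range during simulation)."""
        age = np.atleast_1d(np.asarray(age))
        sex = np.atleast_1d(np.asarray(sex, dtype=object))
        los = np.array([b[0] for b in self.age_bands])
        if (age < los[0]).any():
            raise DomainError(f"age below the first modelled band {self.age_bands[0]}")
        idx = np.clip(np.searchsorted(los, age, side="right") - 1, 0, len(los) - 1)
        table = np.array(
            [
                [self.calibration.get((band, s), 1.0) for s in ("male", "female")]
                for band in self.age_bands
            ]
        )
        female = (sex == "female").astype(int)
        return table[idx, female]


def _band_of(age: float, bands) -> tuple[int, int]:
    for lo, hi in bands:
        if lo <= age <= hi:
            return (lo, hi)
    # ages past the last band (cohort members age during simulation)
    if age > bands[-1][1]:
        return bands[-1]
    raise DomainError(f"age {age} below the first modelled band {bands[0]}")


def load_risk_parameters(path=None) -> RiskParameters:
    """Load the risk-equation coefficient file (default: packaged data)."""
    if path is None:
        path = importlib.resources.files("cvdprevent.data") / "framingham_cvd_1991.csv"
    df = pd.read_csv(path, comment="#")
    coeffs = dict(zip(df["term"], df["value"].astype(float)))
    return RiskParameters(coefficients=coeffs)


def untreated_profile(
    population: pd.DataFrame, adj: TreatmentAdjustment | None = None
) -> pd.DataFrame:
    """Return a copy with treated individuals rolled back to untreated levels.

    Blood-pressure reductions are additive, lipid effects proportional, so the
    reversal adds the mmHg back and divides lipids by (1 -/+ fraction).
    Untreated individuals are returned unchanged.
    """
    adj = adj or TreatmentAdjustment()
    out = population.copy()
    bp = out["on_bp_drugs"].to_numpy(dtype=bool)
    lip = out["on_lipid_drugs"].to_numpy(dtype=bool)
    out.loc[bp, "sbp"] += adj.sbp_reduction
    out.loc[bp, "dbp"] += adj.dbp_reduction
    out.loc[lip, "total_chol"] /= 1.0 - adj.tc_reduction_frac
    out.loc[lip, "hdl_chol"] /= 1.0 + adj.hdl_increase_frac
    out.loc[lip, "triglycerides"] /= 1.0 - adj.tg_reduction_frac
    return out


def _linear_predictor(population: pd.DataFrame, c: dict[str, float]) -> np.ndarray:
    female = (population["sex"] == "female").to_numpy(dtype=float)
    diabetes = population["diabetes"].to_numpy(dtype=float)
    lvh = (
        population["lvh"].to_numpy(dtype=float)
        if "lvh" in population.columns
        else np.zeros(len(population))
    )
    ln_age = np.log(population["age"].to_numpy(dtype=float))
    return (
        c["intercept"]
        + c["female"] * female
        + c["ln_age"] * ln_age
        + c["female_ln_age"] * female * ln_age
        + c["ln_sbp"] * np.log(population["sbp"].to_numpy(dtype=float))
        + c["smoker"] * population["smoker"].to_numpy(dtype=float)
        + c["ln_tc_hdl_ratio"]
        * np.log(
            population["total_chol"].to_numpy(dtype=float)
            / population["hdl_chol"].to_numpy(dtype=float)
        )
        + c["diabetes"] * diabetes
        + c["female_diabetes"] * female * diabetes
        + c["lvh"] * lvh
    )


def five_year_risk(
    population: pd.DataFrame,
    params: RiskParameters,
    horizon_years: float = 5.0,
    calibrated: bool = True,
) -> np.ndarray:
    """Probability of a first fatal or non-fatal IHD/stroke event within
    ``horizon_years``, per row of ``population`` (untreated-equivalent form).

    The Weibull AFT form: u = (ln t - mu) / sigma, p = 1 - exp(-exp(u)),
    with sigma = exp(sigma_const + sigma_mu * mu).  The result is multiplied
    by the individual's calibration factor and clipped to (0, 1).
    """
    c = params.coefficients
    mu = _linear_predictor(population, c)
    sigma = np.exp(c["sigma_const"] + c["sigma_mu"] * mu)
    u = (np.log(horizon_years) - mu) / sigma
    p = 1.0 - np.exp(-np.exp(u))
    if calibrated:
        p = p * params.calibration_factor(
            population["age"].to_numpy(), population["sex"].to_numpy()
        )
    return np.clip(p, *RISK_CLIP)


def calibrate(
    population: pd.DataFrame,
    schedule: EpiSchedule,
    params: RiskParameters,
) -> RiskParameters:
    """Scale predicted risk so cell-mean risk matches schedule-implied risk.

    For every age-band x sex cell the target is the weight-averaged five-year
    first-event probability 1 - exp(-5 (i_ihd + i_stroke)) at the members'
    ages, and the cell's factor is multiplied by target / current cell mean.
    The operation is idempotent: recalibrating calibrated parameters leaves
    the factors unchanged (up to floating point).
    """
    pop = population
    weights = pop["weight"].to_numpy(dtype=float)
    risk_now = five_year_risk(pop, params)
    ages = np.minimum(pop["age"].to_numpy(dtype=int), 100)
    sexes = pop["sex"].to_numpy()
    rate = schedule.lookup("incidence_ihd", ages, sexes) + schedule.lookup(
        "incidence_stroke", ages, sexes
    )
    target_i = 1.0 - np.exp(-5.0 * rate)
    if (target_i >= 1.0).any():
        raise ConfigurationError("schedule incidence implies five-year probability >= 1")

    bands = [_band_of(a, params.age_bands) for a in pop["age"]]
    cells = pd.DataFrame(
        {"band": bands, "sex": pop["sex"].to_numpy(), "w": weights,
         "risk": risk_now, "target": target_i}
    )
    new_cal = dict(params.calibration)
    empty = [
        (band, sex)
        for band in params.age_bands
        for sex in ("male", "female")
        if not ((cells["band"] == band) & (cells["sex"] == sex)).any()
    ]
    if empty:
        raise CalibrationError(f"no individuals in calibration cells: {empty}")
    for (band, sex), grp in cells.groupby(["band", "sex"], sort=False):
        mean_risk = np.average(grp["risk"], weights=grp["w"])
        mean_target = np.average(grp["target"], weights=grp["w"])
        old = params.calibration.get((band, sex), 1.0)
        new_cal[(band, sex)] = old * mean_target / mean_risk
    return replace(params, calibration=new_cal)


def calibration_to_frame(params: RiskParameters) -> pd.DataFrame:
    """Export calibration factors as (age_band, sex, factor) rows."""
    rows = [
        {"age_lo": band[0], "age_hi": band[1], "sex": sex, "factor": f}
        for (band, sex), f in sorted(params.calibration.items())
    ]
    return pd.DataFrame(rows, columns=["age_lo", "age_hi", "sex", "factor"])


def five_to_ten_year(p5) -> np.ndarray | float:
    """Extend a five-year risk to ten years under a constant hazard:
    p10 = 1 - (1 - p5)^2, e.g. 5% -> 9.75% (~10%), 10% -> 19% (~20%)."""
    p5_arr = np.asarray(p5, dtype=float)
    if np.any((p5_arr < 0.0) | (p5_arr > 1.0)):
        raise DomainError("five-year risk must lie in [0, 1]")
    out = 1.0 - (1.0 - p5_arr) ** 2
    return float(out) if np.isscalar(p5) or out.ndim == 0 else out
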