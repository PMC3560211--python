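"""Synthetic survey population and epidemiological input schedules.

The real analysis is driven by an Australian risk-factor survey (individual
blood pressure, lipid, smoking, diabetes and drug-use records for adults with
no history of heart disease or stroke) and by national age/sex schedules of
disease incidence, case fatality and mortality.  Neither data source is
redistributable, so this module generates stand-ins with the statistical
structure the analysis relies on:

* continuous risk factors are drawn from a multivariate normal on
  (SBP, DBP, ln TC, ln HDL, ln TG) so that the positive correlations the
  screening rules and the multivariable risk score jointly exploit are
  present, with log transforms keeping lipids positive;
* current preventive-drug use is assigned with probability increasing in age
  and in the individual's own blood-pressure / cholesterol percentile —
  imperfect but non-random targeting, which is what makes a comparison of
  "current practice" against rule-based eligibility informative;
* incidence, case fatality and background mortality rise exponentially with
  age (log-linear in age per disease and sex).

All generators are deterministic given (n, seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "AGE_BANDS",
    "IndividualRecord",
    "PopulationConfig",
    "EpiScheduleConfig",
    "EpiSchedule",
    "generate_population",
    "generate_epi_schedule",
    "population_to_records",
    "write_population_csv",
    "read_population_csv",
]

#: Default age bands, shared with screening (GP-attendance grid bands).
AGE_BANDS: tuple[tuple[int, int], ...] = (
    (35, 44),
    (45, 54),
    (55, 64),
    (65, 74),
    (75, 84),
)

POPULATION_COLUMNS = [
    "id",
    "age",
    "sex",
    "sbp",
    "dbp",
    "total_chol",
    "hdl_chol",
    "triglycerides",
    "smoker",
    "diabetes",
    "on_bp_drugs",
    "on_lipid_drugs",
    "weight",
]


@dataclass(frozen=True)
class IndividualRecord:
    """One synthetic survey participant with no history of CVD."""

    id: int
    age: int
    sex: str
    sbp: float
    dbp: float
    total_chol: float
    hdl_chol: float
    triglycerides: float
    smoker: bool
    diabetes: bool
    on_bp_drugs: bool
    on_lipid_drugs: bool
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not (35 <= self.age <= 84):
            raise ConfigurationError(f"age: {self.age} outside the modelled 35-84 range")
        if self.sex not in ("male", "female"):
            raise ConfigurationError(f"sex: {self.sex!r} must be 'male' or 'female'")
        if not (self.sbp > self.dbp > 0):
            raise ConfigurationError("sbp/dbp: require sbp > dbp > 0")
        if not (self.total_chol > self.hdl_chol > 0):
            raise ConfigurationError("total_chol/hdl_chol: require TC > HDL > 0")
        if self.triglycerides <= 0:
            raise ConfigurationError("triglycerides: must be positive")
        if self.weight < 0:
            raise ConfigurationError("weight: must be non-negative")


def _default_correlation() -> np.ndarray:
    # order: sbp, dbp, ln TC, ln HDL, ln TG
    return np.array(
        [
            [1.00, 0.70, 0.20, -0.10, 0.15],
            [0.70, 1.00, 0.15, -0.05, 0.15],
            [0.20, 0.15, 1.00, -0.15, 0.35],
            [-0.10, -0.05, -0.15, 1.00, -0.35],
            [0.15, 0.15, 0.35, -0.35, 1.00],
        ]
    )


@dataclass
class PopulationConfig:
    """Distributional settings for the synthetic survey population.

    Continuous risk-factor means are specified at the reference age
    (``ref_age``) with linear per-year age slopes; the joint distribution is
    multivariate normal on (sbp, dbp, ln TC, ln HDL, ln TG) with the given
    marginal SDs and correlation matrix, truncated to physiologic ranges.
    """

    age_bands: tuple[tuple[int, int], ...] = AGE_BANDS
    band_weights: tuple[float, ...] = (0.28, 0.25, 0.21, 0.15, 0.11)
    female_fraction: float = 0.51
    ref_age: float = 55.0

    sbp_mean: float = 127.0
    sbp_slope: float = 0.55      # mmHg per year of age
    sbp_sd: float = 15.0
    dbp_mean: float = 79.0
    dbp_slope: float = 0.10
    dbp_sd: float = 10.0
    ln_tc_mean: float = 1.70     # ~5.5 mmol/L
    ln_tc_slope: float = 0.002
    ln_tc_sd: float = 0.17
    ln_hdl_mean: float = 0.26    # ~1.3 mmol/L
    ln_hdl_female_shift: float = 0.12
    ln_hdl_sd: float = 0.22
    ln_tg_mean: float = 0.35     # ~1.4 mmol/L
    ln_tg_slope: float = 0.002
    ln_tg_sd: float = 0.45
    correlation: np.ndarray = field(default_factory=_default_correlation)

    smoking_prev_at_ref: float = 0.20
    smoking_prev_slope: float = -0.003   # per year of age
    diabetes_prev_at_ref: float = 0.07
    diabetes_prev_slope: float = 0.003

    # current preventive drug use: marginal prevalences plus targeting tilts
    bp_drug_prevalence: float = 0.12
    lipid_drug_prevalence: float = 0.09
    drug_use_age_tilt: float = 0.06      # log-weight per year of age
    drug_use_riskfactor_tilt: float = 1.5  # log-weight per unit percentile
    both_drug_boost: float = 3.0         # relative lipid-use odds if on BP drugs

    total_persons: float | None = None   # scale of record weights; None -> 1/record

    def validate(self) -> None:
        for name in ("sbp_sd", "dbp_sd", "ln_tc_sd", "ln_hdl_sd", "ln_tg_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name}: standard deviation must be non-negative")
        for name in (
            "female_fraction",
            "smoking_prev_at_ref",
            "diabetes_prev_at_ref",
            "bp_drug_prevalence",
            "lipid_drug_prevalence",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name}: {v} is not a probability")
        if len(self.band_weights) != len(self.age_bands):
            raise ConfigurationError("band_weights: length must match age_bands")
        bw = np.asarray(self.band_weights, dtype=float)
        if (bw < 0).any() or bw.sum() <= 0:
            raise ConfigurationError("band_weights: must be non-negative with positive sum")
        corr = np.asarray(self.correlation, dtype=float)
        if corr.shape != (5, 5) or not np.allclose(corr, corr.T):
            raise ConfigurationError("correlation: must be a symmetric 5x5 matrix")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ConfigurationError("correlation: matrix not positive semi-definite")


def generate_population(
    n: int,
    seed: int,
    config: PopulationConfig | None = None,
) -> pd.DataFrame:
    """Generate ``n`` synthetic participants as a DataFrame.

    Columns match :class:`IndividualRecord` fields.  Output is identical for
    identical ``(n, seed, config)``.
    """
    if n < 1:
        raise ConfigurationError("n: must be at least 1")
    cfg = config or PopulationConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)

    bw = np.asarray(cfg.band_weights, dtype=float)
    bw = bw / bw.sum()
    band_idx = rng.choice(len(cfg.age_bands), size=n, p=bw)
    lo = np.array([b[0] for b in cfg.age_bands])[band_idx]
    hi = np.array([b[1] for b in cfg.age_bands])[band_idx]
    age = rng.integers(lo, hi + 1)
    female = rng.random(n) < cfg.female_fraction
    sex = np.where(female, "female", "male")

    d_age = age - cfg.ref_age
    mean = np.column_stack(
        [
            cfg.sbp_mean + cfg.sbp_slope * d_age,
            cfg.dbp_mean + cfg.dbp_slope * d_age,
            cfg.ln_tc_mean + cfg.ln_tc_slope * d_age,
            cfg.ln_hdl_mean + cfg.ln_hdl_female_shift * female,
            cfg.ln_tg_mean + cfg.ln_tg_slope * d_age,
        ]
    )
    sd = np.array([cfg.sbp_sd, cfg.dbp_sd, cfg.ln_tc_sd, cfg.ln_hdl_sd, cfg.ln_tg_sd])
    corr = np.asarray(cfg.correlation, dtype=float)
    cov = corr * np.outer(sd, sd)
    # eigendecomposition rather than Cholesky: PSD (singular) matrices allowed
    w, v = np.linalg.eigh(cov)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal((n, 5))
    x = mean + z @ root.T

    sbp = np.clip(x[:, 0], 85.0, 230.0)
    dbp = np.clip(x[:, 1], 45.0, 135.0)
    dbp = np.minimum(dbp, sbp - 10.0)  # truncation: keep sbp > dbp
    tc = np.clip(np.exp(x[:, 2]), 2.5, 14.0)
    hdl = np.clip(np.exp(x[:, 3]), 0.4, 3.5)
    hdl = np.minimum(hdl, tc - 0.5)    # truncation: keep TC > HDL
    tg = np.clip(np.exp(x[:, 4]), 0.3, 12.0)

    smoker = rng.random(n) < np.clip(
        cfg.smoking_prev_at_ref + cfg.smoking_prev_slope * d_age, 0.0, 1.0
    )
    diabetes = rng.random(n) < np.clip(
        cfg.diabetes_prev_at_ref + cfg.diabetes_prev_slope * d_age, 0.0, 1.0
    )

    # drug use: prevalence-preserving exponential tilt in age and in the
    # individual's own risk-factor percentile (imperfect targeting)
    def _tilted_prob(prev: float, percentile: np.ndarray) -> np.ndarray:
        logw = cfg.drug_use_age_tilt * (age - np.mean(age)) + cfg.drug_use_riskfactor_tilt * (
            percentile - 0.5
        )
        w_ = np.exp(logw - logw.max())
        p = prev * w_ / w_.mean()
        return np.clip(p, 0.0, 0.95)

    pct_sbp = pd.Series(sbp).rank(pct=True).to_numpy()
    pct_tc = pd.Series(tc).rank(pct=True).to_numpy()
    p_bp = _tilted_prob(cfg.bp_drug_prevalence, pct_sbp)
    on_bp = rng.random(n) < p_bp
    p_lip = _tilted_prob(cfg.lipid_drug_prevalence, pct_tc)
    if cfg.bp_drug_prevalence > 0 and cfg.both_drug_boost != 1.0:
        # tilt lipid use toward BP users while preserving the marginal
        pb = float(np.mean(p_bp))
        off_factor = max((1.0 - pb * cfg.both_drug_boost) / (1.0 - pb), 0.0)
        p_lip = np.clip(p_lip * np.where(on_bp, cfg.both_drug_boost, off_factor), 0.0, 0.95)
    on_lip = rng.random(n) < p_lip

    weight = np.full(n, 1.0 if cfg.total_persons is None else cfg.total_persons / n)

    return pd.DataFrame(
        {
            "id": np.arange(n, dtype=int),
            "age": age.astype(int),
            "sex": sex,
            "sbp": sbp,
            "dbp": dbp,
            "total_chol": tc,
            "hdl_chol": hdl,
            "triglycerides": tg,
            "smoker": smoker,
            "diabetes": diabetes,
            "on_bp_drugs": on_bp,
            "on_lipid_drugs": on_lip,
            "weight": weight,
        }
    )


def population_to_records(population: pd.DataFrame) -> list[IndividualRecord]:
    """Materialise a population DataFrame as validated records."""
    return [
        IndividualRecord(**{k: row[k] for k in POPULATION_COLUMNS})
        for row in population.to_dict("records")
    ]


def write_population_csv(population: pd.DataFrame, path) -> None:
    population[POPULATION_COLUMNS].to_csv(path, index=False)


def read_population_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(POPULATION_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"population file missing columns: {sorted(missing)}")
    for col in ("smoker", "diabetes", "on_bp_drugs", "on_lipid_drugs"):
        df[col] = df[col].astype(bool)
    return df


# ---------------------------------------------------------------------------
# Epidemiological schedules
# ---------------------------------------------------------------------------

AGE_MIN, AGE_MAX = 35, 100
SEXES = ("male", "female")
SEX_INDEX = {"male": 0, "female": 1}


@dataclass
class EpiScheduleConfig:
    """Log-linear-in-age shape settings for the synthetic epi schedules.

    Rates are events per person-year at ``ref_age`` with exponential age
    slopes (per year); case fatality is a per-event probability with the same
    exponential-in-age form.  All defaults are synthetic stand-ins for
    national hospital/mortality-register rates, chosen to be plausible for a
    high-income population; they are not fitted to any real registry.
    """

    ref_age: float = 60.0
    ihd_incidence_at_ref: tuple[float, float] = (0.006, 0.003)      # (male, female)
    ihd_incidence_slope: float = 0.075
    stroke_incidence_at_ref: tuple[float, float] = (0.0030, 0.0025)
    stroke_incidence_slope: float = 0.085
    ihd_case_fatality_at_ref: tuple[float, float] = (0.22, 0.20)
    ihd_case_fatality_slope: float = 0.030
    stroke_case_fatality_at_ref: tuple[float, float] = (0.20, 0.18)
    stroke_case_fatality_slope: float = 0.032
    background_mortality_at_ref: tuple[float, float] = (0.0055, 0.0035)
    background_mortality_slope: float = 0.095
    trend_incidence_ihd: float = -0.02      # annual proportional change
    trend_incidence_stroke: float = -0.02
    trend_case_fatality_ihd: float = -0.02
    trend_case_fatality_stroke: float = -0.02
    utility_at_35: float = 0.93
    utility_slope: float = -0.0035          # per year of age
    disability_weight_ihd: float = 0.15
    disability_weight_stroke: float = 0.30

    def validate(self) -> None:
        for name in (
            "ihd_incidence_at_ref",
            "stroke_incidence_at_ref",
            "background_mortality_at_ref",
        ):
            if min(getattr(self, name)) < 0:
                raise ConfigurationError(f"{name}: rates must be non-negative")
        for name, slope in (
            ("ihd_case_fatality", self.ihd_case_fatality_slope),
            ("stroke_case_fatality", self.stroke_case_fatality_slope),
        ):
            base = max(getattr(self, f"{name}_at_ref"))
            if not (0.0 <= base <= 1.0):
                raise ConfigurationError(f"{name}_at_ref: not a probability")
            at_100 = base * np.exp(slope * (AGE_MAX - self.ref_age))
            if at_100 > 1.0:
                raise ConfigurationError(
                    f"{name}_slope: implies case-fatality probability {at_100:.3f} > 1 at age 100"
                )
        for name in ("disability_weight_ihd", "disability_weight_stroke", "utility_at_35"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ConfigurationError(f"{name}: must lie in [0, 1]")
        for name in ("trend_incidence_ihd", "trend_incidence_stroke",
                     "trend_case_fatality_ihd", "trend_case_fatality_stroke"):
            if getattr(self, name) <= -1.0:
                raise ConfigurationError(f"{name}: annual change must exceed -100%")


@dataclass
class EpiSchedule:
    """Age x sex grids of rates and weights, ages 35-100 inclusive.

    Arrays are shaped ``(n_ages, 2)`` with column order (male, female); rates
    are events per person-year, case fatality is probability per event.
    Calendar-year trends are scalar annual proportional changes applied
    multiplicatively by the Markov engine.
    """

    ages: np.ndarray
    incidence_ihd: np.ndarray
    incidence_stroke: np.ndarray
    case_fatality_ihd: np.ndarray
    case_fatality_stroke: np.ndarray
    background_mortality: np.ndarray
    utility_weight: np.ndarray
    trend_incidence: dict[str, float]
    trend_case_fatality: dict[str, float]
    disability_weight_ihd: float
    disability_weight_stroke: float

    _GRIDS = (
        "incidence_ihd",
        "incidence_stroke",
        "case_fatality_ihd",
        "case_fatality_stroke",
        "background_mortality",
        "utility_weight",
    )

    def validate(self) -> None:
        for name in self._GRIDS:
            arr = getattr(self, name)
            if arr.shape != (len(self.ages), 2):
                raise ConfigurationError(f"{name}: wrong shape {arr.shape}")
            if (arr < 0).any():
                raise ConfigurationError(f"{name}: negative values")
        for name in ("case_fatality_ihd", "case_fatality_stroke", "utility_weight"):
            if (getattr(self, name) > 1).any():
                raise ConfigurationError(f"{name}: probabilities/weights must be <= 1")
        for dw in (self.disability_weight_ihd, self.disability_weight_stroke):
            if not (0.0 <= dw <= 1.0):
                raise ConfigurationError("disability weights must lie in [0, 1]")

    def _age_idx(self, age) -> np.ndarray:
        idx = np.asarray(age, dtype=int) - AGE_MIN
        if np.any(idx < 0) or np.any(idx > AGE_MAX - AGE_MIN):
            raise ConfigurationError(f"age outside schedule range {AGE_MIN}-{AGE_MAX}")
        return idx

    def lookup(self, quantity: str, age, sex, year: int = 0):
        """Value of a grid quantity at (age, sex), with trend applied for
        incidence and case fatality when ``year > 0``."""
        arr = getattr(self, quantity)
        sex_idx = SEX_INDEX[sex] if isinstance(sex, str) else np.asarray(
            [SEX_INDEX[s] for s in sex]
        )
        val = arr[self._age_idx(age), sex_idx]
        if quantity.startswith("incidence_"):
            val = val * (1.0 + self.trend_incidence[quantity.split("_", 1)[1]]) ** year
        elif quantity.startswith("case_fatality_"):
            val = np.clip(
                val * (1.0 + self.trend_case_fatality[quantity.split("_", 2)[2]]) ** year,
                0.0,
                1.0,
            )
        return val

    def copy(self) -> "EpiSchedule":
        return replace(
            self,
            ages=self.ages.copy(),
            **{g: getattr(self, g).copy() for g in self._GRIDS},
            trend_incidence=dict(self.trend_incidence),
            trend_case_fatality=dict(self.trend_case_fatality),
        )

    # -- CSV long-format round trip -------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in self._GRIDS:
            arr = getattr(self, name)
            for j, sex in enumerate(SEXES):
                rows.append(
                    pd.DataFrame(
                        {"age": self.ages, "sex": sex, "year": 0,
                         "quantity": name, "value": arr[:, j]}
                    )
                )
        scalars = {
            "trend_incidence_ihd": self.trend_incidence["ihd"],
            "trend_incidence_stroke": self.trend_incidence["stroke"],
            "trend_case_fatality_ihd": self.trend_case_fatality["ihd"],
            "trend_case_fatality_stroke": self.trend_case_fatality["stroke"],
            "disability_weight_ihd": self.disability_weight_ihd,
            "disability_weight_stroke": self.disability_weight_stroke,
        }
        rows.append(
            pd.DataFrame(
                {"age": -1, "sex": "all", "year": 0,
                 "quantity": list(scalars), "value": list(scalars.values())}
            )
        )
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EpiSchedule":
        ages = np.arange(AGE_MIN, AGE_MAX + 1)
        grids = {}
        for name in cls._GRIDS:
            arr = np.zeros((len(ages), 2))
            for j, sex in enumerate(SEXES):
                sub = df[(df["quantity"] == name) & (df["sex"] == sex)].set_index("age")
                arr[:, j] = sub.loc[ages, "value"].to_numpy()
            grids[name] = arr
        scal = df[df["sex"] == "all"].set_index("quantity")["value"]
        sched = cls(
            ages=ages,
            trend_incidence={"ihd": float(scal["trend_incidence_ihd"]),
                             "stroke": float(scal["trend_incidence_stroke"])},
            trend_case_fatality={"ihd": float(scal["trend_case_fatality_ihd"]),
                                 "stroke": float(scal["trend_case_fatality_stroke"])},
            disability_weight_ihd=float(scal["disability_weight_ihd"]),
            disability_weight_stroke=float(scal["disability_weight_stroke"]),
            **grids,
        )
        sched.validate()
        return sched

    @classmethod
    def from_csv(cls, path) -> "EpiSchedule":
        return cls.from_frame(pd.read_csv(path))


def generate_epi_schedule(
    seed: int = 0, config: EpiScheduleConfig | None = None
) -> EpiSchedule:
    """Build the synthetic age/sex schedules (deterministic; exponential in age).

    ``seed`` is accepted for interface symmetry with the population generator;
    the default construction is closed-form and does not consume randomness.
    """
    cfg = config or EpiScheduleConfig()
    cfg.validate()
    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    d = (ages - cfg.ref_age)[:, None]

    def expo(base: tuple[float, float], slope: float) -> np.ndarray:
        return np.asarray(base)[None, :] * np.exp(slope * d)

    sched = EpiSchedule(
        ages=ages,
        incidence_ihd=expo(cfg.ihd_incidence_at_ref, cfg.ihd_incidence_slope),
        incidence_stroke=expo(cfg.stroke_incidence_at_ref, cfg.stroke_incidence_slope),
        case_fatality_ihd=np.clip(
            expo(cfg.ihd_case_fatality_at_ref, cfg.ihd_case_fatality_slope), 0, 1
        ),
        case_fatality_stroke=np.clip(
            expo(cfg.stroke_case_fatality_at_ref, cfg.stroke_case_fatality_slope), 0, 1
        ),
        background_mortality=expo(
            cfg.background_mortality_at_ref, cfg.background_mortality_slope
        ),
        utility_weight=np.clip(
            cfg.utility_at_35 + cfg.utility_slope * (ages - 35.0), 0.0, 1.0
        )[:, None].repeat(2, axis=1),
        trend_incidence={"ihd": cfg.trend_incidence_ihd,
                         "stroke": cfg.trend_incidence_stroke},
        trend_case_fatality={"ihd": cfg.trend_case_fatality_ihd,
                             "stroke": cfg.trend_case_fatality_stroke},
        disability_weight_ihd=cfg.disability_weight_ihd,
        disability_weight_stroke=cfg.disability_weight_stroke,
    )
    sched.validate()
    return sched
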