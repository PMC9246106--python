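"""Per-agent annual event probabilities and risk-factor dynamics.

The annual first/subsequent-MI probability is a multiplicative log-linear
hazard model anchored at fixed reference levels: a time-invariant baseline
hazard by sex and single year of age is scaled by relative risks per
stated increment of each continuous factor (5 kg/m^2 BMI, 10 mmHg SBP,
1 mmol/L cholesterol) and per binary factor, then converted to a
probability via ``p = 1 - exp(-h)``.  Population-level change over time
comes only from risk-factor trends and the case-fatality trend — the
baseline schedule itself never changes.

Both scalar (one :class:`~micromi.population.Agent`) and vectorised
(arrays over a whole population) entry points are provided; the scalar
forms delegate to the array forms so there is a single code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .params import ParameterVector, ReferenceLevels
from .population import PLAUSIBLE_RANGES, Agent, LifeTable

__all__ = [
    "BaselineIncidenceSchedule",
    "default_schedule",
    "annual_mi_probability",
    "annual_mi_probability_arrays",
    "case_fatality_probability",
    "non_mi_death_probability",
    "update_risk_factors",
    "update_risk_factors_arrays",
]

BASE_YEAR = 1998          # anchor for the case-fatality trend
CF_REF_AGE = 70           # age at which cf_base applies
CF_FEMALE_OFFSET = 0.20   # fixed log-odds offset for women (not calibrated)


@dataclass
class BaselineIncidenceSchedule:
    """Time-invariant annual first-MI hazard at reference risk-factor
    levels, by sex and single year of age."""

    ages: np.ndarray
    hazard: dict[str, np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        for sex, arr in self.hazard.items():
            if arr.shape != self.ages.shape:
                raise ValueError(f"schedule block for {sex} has wrong shape")
            if (arr < 0).any():
                raise ValueError("baseline hazards must be non-negative")

    def __call__(self, sex: str, age: int) -> float:
        return float(self.hazard[sex][self._idx(np.asarray([age]))[0]])

    def lookup_array(self, sex_male: np.ndarray, age: np.ndarray) -> np.ndarray:
        idx = self._idx(age)
        return np.where(sex_male, self.hazard["male"][idx], self.hazard["female"][idx])

    def _idx(self, age: np.ndarray) -> np.ndarray:
        if age.size and (age.min() < self.ages[0] or age.max() > self.ages[-1]):
            raise KeyError(f"age outside schedule range [{self.ages[0]}, {self.ages[-1]}]")
        return (np.asarray(age) - self.ages[0]).astype(np.intp)


def default_schedule(ages: tuple[int, int] = (0, 150),
                     anchor_age: int = 70,
                     anchor_hazard: float = 0.0015,
                     doubling_years: float = 8.0,
                     plateau_age: int = 90,
                     female_ratio: float = 0.5) -> BaselineIncidenceSchedule:
    """Exponential-in-age baseline hazard at reference risk-factor levels.

    Doubles every ``doubling_years`` of age up to ``plateau_age``, then
    flattens (MI incidence stops rising in the very old).  The anchor of
    0.15%/year for men at 70 refers to an agent at *reference* factor
    levels; typical elderly profiles carry multiplicative relative risks
    of ~4-6, landing effective incidence at observed magnitudes.  The
    calibrated ``baseline_scale`` multiplies the whole schedule, so the
    anchor is a convenience, not a claim."""
    age_arr = np.arange(ages[0], ages[1] + 1)
    eff_age = np.minimum(age_arr, plateau_age)
    male = anchor_hazard * 2.0 ** ((eff_age - anchor_age) / doubling_years)
    return BaselineIncidenceSchedule(
        ages=age_arr, hazard={"male": male, "female": female_ratio * male})


# ---------------------------------------------------------------------------
# Event probabilities

def annual_mi_probability_arrays(sex_male: np.ndarray, age: np.ndarray,
                                 bmi: np.ndarray, sbp: np.ndarray, tchol: np.ndarray,
                                 smoker: np.ndarray, diabetic: np.ndarray,
                                 prior_mi: np.ndarray,
                                 params: ParameterVector,
                                 schedule: BaselineIncidenceSchedule,
                                 refs: ReferenceLevels | None = None) -> np.ndarray:
    refs = refs or ReferenceLevels()
    h = params.baseline_scale * schedule.lookup_array(sex_male, age)
    h = h * params.rr_bmi ** ((bmi - refs.bmi_ref) / 5.0)
    h = h * params.rr_sbp ** ((sbp - refs.sbp_ref) / 10.0)
    h = h * params.rr_tchol ** (tchol - refs.tchol_ref)
    h = h * np.where(smoker, params.rr_smoking, 1.0)
    h = h * np.where(diabetic, params.rr_diabetes, 1.0)
    h = h * np.where(prior_mi, params.rr_prior_mi, 1.0)
    return -np.expm1(-h)


def annual_mi_probability(agent: Agent, params: ParameterVector,
                          schedule: BaselineIncidenceSchedule,
                          refs: ReferenceLevels | None = None) -> float:
    """Annual probability of an MI event for one living agent.

    Raises if the agent is dead or the age falls outside the schedule.
    """
    if not agent.alive:
        raise ValueError("annual_mi_probability requires a living agent")
    p = annual_mi_probability_arrays(
        np.array([agent.sex == "male"]), np.array([agent.age]),
        np.array([agent.bmi]), np.array([agent.sbp]), np.array([agent.tchol]),
        np.array([agent.smoker]), np.array([agent.diabetic]),
        np.array([agent.prior_mi]), params, schedule, refs)
    return float(p[0])


def case_fatality_probability(sex, age, year, params: ParameterVector,
                              base_year: int = BASE_YEAR):
    """30-day case fatality for an MI in a given calendar year.

    Logistic in age around age 70 with a fixed sex offset; the base-year
    probability declines geometrically at rate ``cf_trend`` per year,
    proxying treatment improvement.  Accepts scalars or arrays.
    """
    sex_male = np.asarray(sex == "male") if isinstance(sex, str) else np.asarray(sex)
    age = np.asarray(age, dtype=float)
    lo = (logit(params.cf_base)
          + params.cf_age_slope * (age - CF_REF_AGE)
          + np.where(sex_male, 0.0, CF_FEMALE_OFFSET))
    p = expit(lo) * (1.0 - params.cf_trend) ** (year - base_year)
    p = np.clip(p, 0.0, 1.0)
    return float(p) if p.ndim == 0 else p


def non_mi_death_probability(agent: Agent, life_table: LifeTable, year: int) -> float:
    """Exogenous annual probability of death from non-MI causes.

    By design this depends only on sex, age and calendar year, never on
    the agent's risk factors — a deliberate simplification that tends to
    overstate survival (hence MI prevalence) in high-risk profiles.
    """
    return life_table.lookup(agent.sex, agent.age, year)


# ---------------------------------------------------------------------------
# Risk-factor dynamics

def update_risk_factors_arrays(bmi, sbp, tchol, smoker, diabetic, age,
                               params: ParameterVector,
                               u_quit: np.ndarray, u_diab: np.ndarray):
    """One annual trend update, in place on copies; returns new arrays.

    BMI approaches the asymptote geometrically; SBP and cholesterol drift
    linearly; smoking can only be quit and diabetes only acquired (one-way
    transitions).  Continuous values are re-clamped to plausible ranges.
    """
    bmi = bmi + params.trend_bmi_rate * (params.trend_bmi_asymptote - bmi)
    sbp = sbp + params.trend_sbp_slope
    tchol = tchol + params.trend_tchol_slope
    bmi = np.clip(bmi, *PLAUSIBLE_RANGES["bmi"])
    sbp = np.clip(sbp, *PLAUSIBLE_RANGES["sbp"])
    tchol = np.clip(tchol, *PLAUSIBLE_RANGES["tchol"])
    smoker = smoker & ~(u_quit < params.trend_smoking_quit)
    p_diab = diabetes_incidence(age, params)
    diabetic = diabetic | (u_diab < p_diab)
    return bmi, sbp, tchol, smoker, diabetic


def diabetes_incidence(age, params: ParameterVector):
    """Annual probability of developing diabetes: exponential in age,
    capped, scaled by the calibrated ``trend_diabetes_inc``."""
    base = np.minimum(5e-4 * np.exp(0.05 * (np.asarray(age, float) - 30.0)), 0.05)
    return np.clip(params.trend_diabetes_inc * base, 0.0, 1.0)


def update_risk_factors(agent: Agent, params: ParameterVector, year: int,
                        rng: np.random.Generator) -> Agent:
    """Apply one year of risk-factor trends to a living agent (age is
    incremented by the simulation loop, not here)."""
    if not agent.alive:
        raise ValueError("update_risk_factors requires a living agent")
    u = rng.random(2)
    bmi, sbp, tchol, smoker, diabetic = update_risk_factors_arrays(
        np.array([agent.bmi]), np.array([agent.sbp]), np.array([agent.tchol]),
        np.array([agent.smoker]), np.array([agent.diabetic]),
        np.array([agent.age]), params, u[:1], u[1:2])
    agent.bmi, agent.sbp, agent.tchol = float(bmi[0]), float(sbp[0]), float(tchol[0])
    agent.smoker, agent.diabetic = bool(smoker[0]), bool(diabetic[0])
    return agent
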