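"""The annual-cycle microsimulation.

Each agent is followed over annual time points from the base year to the
horizon.  Within an event year the resolution order is fixed:

1. draw an MI event from the annual MI probability;
2. if an MI occurred, draw 30-day death from the case-fatality
   probability — on death the year ends (MI death);
3. draw other-cause death from the exogenous life table — on death the
   year ends (other death);
4. survivors get their risk factors updated, ``prior_mi`` set if an MI
   occurred, and age incremented.

This order makes MI deaths and other deaths disjoint and every MI event
countable.  Randomness is counter-based: the uniform draws for agent
``i`` in year ``t`` are a deterministic function of ``(seed, id, t)``
alone, so results are invariant to the order in which agents are
processed and to any parallel decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ParameterVector, ReferenceLevels
from .population import Agent, LifeTable, Population
from .risk import (BaselineIncidenceSchedule, annual_mi_probability_arrays,
                   case_fatality_probability, update_risk_factors_arrays)

__all__ = ["SimulationConfig", "SimResult", "simulate_population",
           "step_agent_year", "agent_uniforms", "N_DRAWS_PER_YEAR"]

# Draw layout per agent-year: [mi, case_fatality, other_death, quit, diabetes]
N_DRAWS_PER_YEAR = 5


@dataclass(frozen=True)
class SimulationConfig:
    start_year: int = 1998
    end_year: int = 2035
    seed: int = 0
    calibration_window: tuple[int, int] = (1999, 2011)
    forecast_window: tuple[int, int] = (2017, 2035)

    def __post_init__(self) -> None:
        if self.end_year < self.start_year:
            raise ValueError("end_year must be >= start_year")
        for lo, hi in (self.calibration_window, self.forecast_window):
            if not (self.start_year <= lo <= hi <= self.end_year):
                raise ValueError("windows must lie within [start_year, end_year]")

    @property
    def event_years(self) -> np.ndarray:
        """Years in which events are resolved (the base year holds the
        initial state only)."""
        return np.arange(self.start_year + 1, self.end_year + 1)


@dataclass
class SimResult:
    """Dense per-agent, per-year record of one simulation run.

    All event arrays have shape ``(n_agents, n_years)`` with columns
    aligned to ``years``; ``*_start`` is the state at the start of the
    event year, ``*_end`` after its events resolved.
    """

    years: np.ndarray
    ids: np.ndarray
    sex_male: np.ndarray
    age_start: np.ndarray = field(repr=False)
    alive_start: np.ndarray = field(repr=False)
    prior_start: np.ndarray = field(repr=False)
    alive_end: np.ndarray = field(repr=False)
    prior_end: np.ndarray = field(repr=False)
    first_mi: np.ndarray = field(repr=False)
    recurrent_mi: np.ndarray = field(repr=False)
    mi_death: np.ndarray = field(repr=False)
    other_death: np.ndarray = field(repr=False)

    def event_log(self) -> pd.DataFrame:
        """Long-format event log: one row per (agent, year, event)."""
        rows = []
        for name, arr in (("first_mi", self.first_mi),
                          ("recurrent_mi", self.recurrent_mi),
                          ("mi_death", self.mi_death),
                          ("other_death", self.other_death)):
            a, t = np.nonzero(arr)
            rows.append(pd.DataFrame({"agent_id": self.ids[a],
                                      "year": self.years[t], "event": name}))
        log = pd.concat(rows, ignore_index=True)
        return log.sort_values(["agent_id", "year", "event"]).reset_index(drop=True)

    def final_states(self) -> pd.DataFrame:
        """End-of-simulation vital status per agent."""
        mi_d = self.mi_death.any(axis=1)
        oth_d = self.other_death.any(axis=1)
        cause = np.where(mi_d, "mi", np.where(oth_d, "other", "none"))
        return pd.DataFrame({"agent_id": self.ids,
                             "alive": self.alive_end[:, -1],
                             "prior_mi": self.prior_end[:, -1],
                             "cause_of_death": cause})


def agent_uniforms(seed: int, n_ids: int, n_years: int) -> np.ndarray:
    """Uniform draws indexed by agent id: shape (n_ids, n_years, 5).

    Generated from a counter-based Philox stream keyed by ``seed`` only,
    so the block for agent ``i`` depends on ``(seed, i)`` and never on
    which other agents are simulated first.
    """
    gen = np.random.Generator(np.random.Philox(key=seed))
    return gen.random((n_ids, n_years, N_DRAWS_PER_YEAR))


def _resolve_year(sex_male, age, bmi, sbp, tchol, smoker, diabetic, prior,
                  alive, year, params, schedule, life_table, refs, u):
    """Resolve one event year for a block of agents; returns event flags
    and updated state arrays.  ``u`` has shape (n, 5)."""
    p_mi = np.zeros(len(age))
    if alive.any():
        p_mi[alive] = annual_mi_probability_arrays(
            sex_male[alive], age[alive], bmi[alive], sbp[alive], tchol[alive],
            smoker[alive], diabetic[alive], prior[alive], params, schedule, refs)
    mi = alive & (u[:, 0] < p_mi)

    p_cf = case_fatality_probability(sex_male, age, year, params)
    mi_death = mi & (u[:, 1] < p_cf)

    q_other = np.zeros(len(age))
    at_risk = alive & ~mi_death
    if at_risk.any():
        q_other[at_risk] = life_table.lookup_array(
            sex_male[at_risk], age[at_risk], year)
    other_death = at_risk & (u[:, 2] < q_other)

    survivors = alive & ~mi_death & ~other_death
    first = mi & ~prior
    recurrent = mi & prior

    n_bmi, n_sbp, n_tch, n_smk, n_dia = update_risk_factors_arrays(
        bmi, sbp, tchol, smoker, diabetic, age, params, u[:, 3], u[:, 4])
    bmi = np.where(survivors, n_bmi, bmi)
    sbp = np.where(survivors, n_sbp, sbp)
    tchol = np.where(survivors, n_tch, tchol)
    smoker = np.where(survivors, n_smk, smoker)
    diabetic = np.where(survivors, n_dia, diabetic)
    prior_end = prior | mi
    age = np.where(survivors, age + 1, age)
    return (mi, first, recurrent, mi_death, other_death, survivors,
            bmi, sbp, tchol, smoker, diabetic, prior_end, age)


def simulate_population(population: Population,
                        params: ParameterVector,
                        schedule: BaselineIncidenceSchedule,
                        life_table: LifeTable,
                        config: SimulationConfig,
                        refs: ReferenceLevels | None = None) -> SimResult:
    """Run the full microsimulation for every agent.

    Deterministic given ``config.seed`` and the population; agent
    processing order cannot affect the result because draws are keyed by
    agent id.
    """
    refs = refs or ReferenceLevels()
    frame = population.frame
    n = len(frame)
    years = config.event_years
    T = len(years)

    ids = frame["id"].to_numpy(int) if n else np.empty(0, int)
    if n and ids.min() < 0:
        raise ValueError("agent ids must be non-negative")
    n_ids = int(ids.max()) + 1 if n else 0
    U = agent_uniforms(config.seed, n_ids, T)

    sex_male = (frame["sex"] == "male").to_numpy() if n else np.empty(0, bool)
    age = frame["age"].to_numpy(int).copy() if n else np.empty(0, int)
    bmi = frame["bmi"].to_numpy(float).copy() if n else np.empty(0)
    sbp = frame["sbp"].to_numpy(float).copy() if n else np.empty(0)
    tchol = frame["tchol"].to_numpy(float).copy() if n else np.empty(0)
    smoker = frame["smoker"].to_numpy(bool).copy() if n else np.empty(0, bool)
    diabetic = frame["diabetic"].to_numpy(bool).copy() if n else np.empty(0, bool)
    prior = frame["prior_mi"].to_numpy(bool).copy() if n else np.empty(0, bool)
    alive = np.ones(n, bool)

    shape = (n, T)
    out = {k: np.zeros(shape, bool) for k in
           ("alive_start", "prior_start", "alive_end", "prior_end",
            "first_mi", "recurrent_mi", "mi_death", "other_death")}
    age_start = np.zeros(shape, np.int16)

    for t, year in enumerate(years):
        out["alive_start"][:, t] = alive
        out["prior_start"][:, t] = prior
        age_start[:, t] = age
        (mi, first, recurrent, mi_death, other_death, survivors,
         bmi, sbp, tchol, smoker, diabetic, prior, age) = _resolve_year(
            sex_male, age, bmi, sbp, tchol, smoker, diabetic, prior, alive,
            int(year), params, schedule, life_table, refs, U[ids, t, :])
        out["first_mi"][:, t] = first
        out["recurrent_mi"][:, t] = recurrent
        out["mi_death"][:, t] = mi_death
        out["other_death"][:, t] = other_death
        out["alive_end"][:, t] = survivors
        out["prior_end"][:, t] = prior
        alive = survivors

    return SimResult(years=years, ids=ids, sex_male=sex_male,
                     age_start=age_start, **out)


def step_agent_year(agent: Agent, year: int, params: ParameterVector,
                    schedule: BaselineIncidenceSchedule, life_table: LifeTable,
                    rng: np.random.Generator | np.ndarray,
                    refs: ReferenceLevels | None = None) -> tuple[dict, Agent]:
    """Resolve one event year for a single agent.

    ``rng`` may be a Generator (five uniforms are consumed, matching the
    per-year draw layout of :func:`simulate_population`) or an explicit
    length-5 array of uniforms.  Returns ``(flags, agent)`` where flags
    has keys first_mi/recurrent_mi/mi_death/other_death.
    """
    if not agent.alive:
        raise ValueError("cannot step a dead agent")
    refs = refs or ReferenceLevels()
    u = rng if isinstance(rng, np.ndarray) else rng.random(N_DRAWS_PER_YEAR)
    u = np.asarray(u, float).reshape(1, N_DRAWS_PER_YEAR)

    (mi, first, recurrent, mi_death, other_death, survivors,
     bmi, sbp, tchol, smoker, diabetic, prior, age) = _resolve_year(
        np.array([agent.sex == "male"]), np.array([agent.age]),
        np.array([agent.bmi]), np.array([agent.sbp]), np.array([agent.tchol]),
        np.array([agent.smoker]), np.array([agent.diabetic]),
        np.array([agent.prior_mi]), np.array([True]),
        year, params, schedule, life_table, refs, u)

    flags = {"first_mi": bool(first[0]), "recurrent_mi": bool(recurrent[0]),
             "mi_death": bool(mi_death[0]), "other_death": bool(other_death[0])}
    agent.alive = bool(survivors[0])
    if flags["mi_death"]:
        agent.cause_of_death = "mi"
    elif flags["other_death"]:
        agent.cause_of_death = "other"
    if bool(mi[0]) and not agent.prior_mi:
        agent.prior_mi = True
        agent.year_first_mi = year
    if agent.alive:
        agent.bmi, agent.sbp, agent.tchol = float(bmi[0]), float(sbp[0]), float(tchol[0])
        agent.smoker, agent.diabetic = bool(smoker[0]), bool(diabetic[0])
        agent.age = int(age[0])
    return flags, agent
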