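"""Calibration targets and their synthetic generator.

A calibration target is one external rate estimate with an observation
variance: (year, sex, age group, metric, value, obs_variance).  The real
calibration data for a national model would come from linked hospital
episode / death-certificate statistics (incidence and event rates,
annual) and a health examination survey (prevalence, survey years).
The synthetic generator emulates that shape: it runs the simulator once
at a known "true" parameter vector, extracts the calibration-window
cells, and adds independent Gaussian noise with stated SDs — giving a
ground truth for parameter-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import SimulationConfig, simulate_population
from .params import ParameterVector
from .population import LifeTable, Population
from .rates import AGE_GROUPS, compute_rates
from .risk import BaselineIncidenceSchedule

__all__ = ["TARGET_COLUMNS", "NoiseSpec", "target_name", "generate_synthetic_targets",
           "load_targets", "save_targets", "default_prevalence_years"]

TARGET_COLUMNS = ["year", "sex", "age_group", "metric", "value", "obs_variance"]


@dataclass(frozen=True)
class NoiseSpec:
    """Observation-noise SDs for synthetic targets: relative to the cell
    value with an absolute floor, per metric.  Units: per 100,000 for
    incidence/event floors, proportion for prevalence."""

    rel_incidence: float = 0.05
    rel_event: float = 0.05
    rel_prevalence: float = 0.05
    floor_incidence: float = 20.0
    floor_event: float = 20.0
    floor_prevalence: float = 0.002

    def sd(self, metric: str, value: np.ndarray) -> np.ndarray:
        rel = getattr(self, f"rel_{metric}")
        floor = getattr(self, f"floor_{metric}")
        return np.maximum(rel * np.abs(value), floor)


def default_prevalence_years(window: tuple[int, int]) -> list[int]:
    """Health-survey-style prevalence years within the calibration
    window (the survey series measured CVD prevalence in 1998, 2003,
    2005, 2006 and 2011)."""
    survey_years = [1998, 2003, 2005, 2006, 2011]
    return [y for y in survey_years if window[0] <= y <= window[1]]


def target_name(year: int, sex: str, age_group: str, metric: str) -> str:
    return f"{metric}:{sex}:{age_group}:{year}"


def generate_synthetic_targets(true_params: ParameterVector,
                               population: Population,
                               schedule: BaselineIncidenceSchedule,
                               life_table: LifeTable,
                               config: SimulationConfig,
                               noise: NoiseSpec | None = None,
                               seed: int = 0,
                               prevalence_years: list[int] | None = None) -> pd.DataFrame:
    """Run the simulator once at ``true_params`` and emit noisy targets.

    Incidence and event-rate targets cover every year of the calibration
    window; prevalence targets only the survey-style years.  Noise is
    independent Gaussian with SD from ``noise``; ``obs_variance`` records
    the squared SD.  With a zero-noise spec the targets equal the
    simulated rates exactly.  Cells with empty denominators are dropped.
    Deterministic given ``seed``.
    """
    noise = noise or NoiseSpec()
    lo, hi = config.calibration_window
    if prevalence_years is None:
        prevalence_years = default_prevalence_years((lo, hi))

    sim_config = SimulationConfig(start_year=config.start_year, end_year=hi,
                                  seed=seed,
                                  calibration_window=config.calibration_window,
                                  forecast_window=(hi, hi))
    result = simulate_population(population, true_params, schedule,
                                 life_table, sim_config)
    table = compute_rates(result)

    keep = (
        ((table["metric"].isin(["incidence", "event"]))
         & table["year"].between(lo, hi))
        | ((table["metric"] == "prevalence") & table["year"].isin(prevalence_years))
    )
    cells = table[keep & table["value"].notna()].copy()

    cells = cells.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    sds = np.array([noise.sd(m, v) for m, v in
                    zip(cells["metric"], cells["value"])], float)
    sampling_var = _sampling_variance(cells)
    cells["value"] = cells["value"] + sds * rng.standard_normal(len(cells))
    cells.loc[cells["metric"] == "prevalence", "value"] = \
        cells.loc[cells["metric"] == "prevalence", "value"].clip(lower=0.0, upper=1.0)
    cells.loc[cells["metric"] != "prevalence", "value"] = \
        cells.loc[cells["metric"] != "prevalence", "value"].clip(lower=0.0)
    # total observation variance: injected noise plus the finite-sample
    # variance of the generating run's own rate estimate — a target built
    # from a finite cohort carries that sampling error exactly as real
    # registry/survey estimates carry theirs
    cells["obs_variance"] = sds ** 2 + sampling_var
    out = cells[TARGET_COLUMNS].sort_values(["metric", "sex", "age_group", "year"])
    return out.reset_index(drop=True)


def _sampling_variance(cells: pd.DataFrame) -> np.ndarray:
    """Finite-sample variance of each rate-cell estimate from its own
    denominator: binomial for incidence and prevalence, Poisson-count for
    event rates (which may include several events per person)."""
    value = cells["value"].to_numpy(float)
    denom = cells["denominator"].to_numpy(float)
    metric = cells["metric"].to_numpy()
    var = np.zeros(len(cells))
    inc = metric == "incidence"
    p = value[inc] / 1e5
    var[inc] = p * (1 - p) / denom[inc] * 1e10
    ev = metric == "event"
    var[ev] = value[ev] * 1e5 / denom[ev]
    pr = metric == "prevalence"
    var[pr] = value[pr] * (1 - value[pr]) / denom[pr]
    return var


def save_targets(targets: pd.DataFrame, path: str) -> None:
    targets[TARGET_COLUMNS].to_csv(path, index=False)


def load_targets(path: str) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in TARGET_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"targets CSV missing columns: {missing}")
    if (frame["obs_variance"] <= 0).any():
        raise ValueError("obs_variance must be positive for every target")
    bad = set(frame["age_group"]) - set(AGE_GROUPS)
    if bad:
        raise ValueError(f"unknown age groups in targets: {sorted(bad)}")
    return frame[TARGET_COLUMNS]
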