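"""Emulator-assisted Bayesian history matching and forecasting.

Calibration proceeds in waves.  Each wave runs the simulator at a batch
of parameter vectors, fits an emulator to the calibration-window
outputs, and screens a large candidate sample of parameter space with
the implausibility measure

    I(theta) = |emulator mean - target value|
               / sqrt(emulator variance + observation variance),

retaining vectors whose maximum implausibility over the targets is below
a cutoff (default 3, the three-sigma rule).  Targets whose emulator
diagnostic (held-out correlation) falls below a floor are excluded from
the maximum, concentrating the screen on the outputs the emulator
reproduces well — in practice prevalence and event rates more than
incidence.  Successive waves refocus design and candidates on the
retained region until the retained proportion stabilises, then a final
ensemble is sampled from the non-implausible space and pushed through
the simulator to the horizon for forecasts with percentile uncertainty
bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .emulator import EmulatorModel, TrainingSet, fit_emulator, latin_hypercube
from .engine import SimulationConfig, simulate_population
from .params import ParameterVector, frame_to_vectors
from .population import LifeTable, Population
from .rates import compute_rates, age_standardise, summarise_runs
from .risk import BaselineIncidenceSchedule
from .targets import TARGET_COLUMNS, target_name

__all__ = ["implausibility", "screen", "run_waves", "forecast",
           "HistoryMatchConfig", "WaveState", "SimulatorHarness",
           "DESK_PROFILE", "FULL_PROFILE"]

# Named budget profiles: (n_agents, runs per wave, candidates per wave).
DESK_PROFILE = {"n_agents": 5_000, "n_runs": 120, "n_candidates": 100_000}
FULL_PROFILE = {"n_agents": 114_000, "n_runs": 450, "n_candidates": 2_000_000}


def implausibility(mean, variance, value, obs_variance):
    """Standardised distance between emulated output and target.

    Vectorised over any broadcastable shapes.  If both variances are
    zero the result is 0 where the mean matches the value exactly and
    +inf otherwise (a flagged sentinel, never an exception).
    """
    mean = np.asarray(mean, float)
    variance = np.asarray(variance, float)
    value = np.asarray(value, float)
    obs_variance = np.asarray(obs_variance, float)
    if (variance < 0).any() or (obs_variance < 0).any():
        raise ValueError("variances must be non-negative")
    total = variance + obs_variance
    diff = np.abs(mean - value)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = diff / np.sqrt(total)
    out = np.where(total == 0, np.where(diff == 0, 0.0, np.inf), out)
    return float(out) if out.ndim == 0 else out


@dataclass
class HistoryMatchConfig:
    n_runs: int = DESK_PROFILE["n_runs"]
    n_candidates: int = DESK_PROFILE["n_candidates"]
    cutoff: float = 3.0
    max_waves: int = 3
    rel_tol: float = 0.10          # stop when retention changes < 10% relatively
    ensemble_size: int = 450
    holdout_fraction: float = 0.2
    diag_floor: float = 0.5        # targets below this held-out corr are excluded
    backend: str = "quadratic"
    max_retained_stored: int = 100_000
    fresh_forecast_seeds: bool = True
    seed: int = 0


@dataclass
class WaveState:
    """Record of one history-matching wave."""

    wave: int
    emulator: EmulatorModel
    retained: pd.DataFrame = field(repr=False)
    proportion: float = 0.0              # of the prior space (cumulative)
    conditional_proportion: float = 0.0  # of this wave's candidate pool
    cutoff: float = 3.0
    excluded_targets: list[str] = field(default_factory=list)
    n_candidates: int = 0

    def summary(self) -> dict:
        return {"wave": self.wave, "proportion": self.proportion,
                "conditional_proportion": self.conditional_proportion,
                "cutoff": self.cutoff, "n_candidates": self.n_candidates,
                "n_retained": len(self.retained),
                "n_excluded_targets": len(self.excluded_targets)}


def _active_targets(model: EmulatorModel, targets: pd.DataFrame,
                    diag_floor: float) -> tuple[list[str], list[str]]:
    """Split target names into (used, excluded) by emulator diagnostic."""
    names = [target_name(r.year, r.sex, r.age_group, r.metric)
             for r in targets.itertuples()]
    diag = model.diagnostics
    used, excluded = [], []
    for nm in names:
        d = diag.get(nm, np.nan)
        (excluded if (np.isfinite(d) and d < diag_floor) else used).append(nm)
    if not used:
        raise ValueError("every target fell below the emulator diagnostic floor; "
                         "lower diag_floor or improve the training design")
    return used, excluded


def screen(candidates: pd.DataFrame, model: EmulatorModel,
           targets: pd.DataFrame, cutoff: float = 3.0,
           diag_floor: float = 0.5, block: int = 20_000):
    """Retain candidate vectors whose maximum implausibility over the
    (diagnostic-passing) targets is <= cutoff.

    Returns ``(retained, proportion, max_impl)`` where ``max_impl`` is
    the per-candidate maximum implausibility.  Raises if nothing is
    retained — a signal to review the cutoff or the diagnostics, never a
    silent continuation.
    """
    used, _ = _active_targets(model, targets, diag_floor)
    tmap = {target_name(r.year, r.sex, r.age_group, r.metric): (r.value, r.obs_variance)
            for r in targets.itertuples()}
    values = np.array([tmap[nm][0] for nm in used])
    obs_var = np.array([tmap[nm][1] for nm in used])

    max_i = np.empty(len(candidates))
    for start in range(0, len(candidates), block):
        chunk = candidates.iloc[start:start + block]
        mean, var = model.predict(chunk)
        im = implausibility(mean[used].to_numpy(), var[used].to_numpy(),
                            values[None, :], obs_var[None, :])
        max_i[start:start + len(chunk)] = im.max(axis=1) if im.size else 0.0
    keep = max_i <= cutoff
    proportion = float(keep.mean()) if len(keep) else 0.0
    if not keep.any():
        raise ValueError(
            f"screening retained no candidates at cutoff {cutoff}; "
            "review the cutoff, the emulator diagnostics, or the targets")
    return candidates[keep].reset_index(drop=True), proportion, max_i


def point_in_retained(waves: list[WaveState], theta: pd.DataFrame,
                      targets: pd.DataFrame) -> np.ndarray:
    """Whether parameter vectors lie in the final non-implausible set.

    The retained sets are nested, so membership means passing every
    wave's screen (each with its own emulator and usable targets).
    Returns a boolean per row of ``theta``.
    """
    inside = np.ones(len(theta), bool)
    for w in waves:
        used = [nm for nm in w.emulator.output_names
                if nm not in w.excluded_targets]
        tmap = {target_name(r.year, r.sex, r.age_group, r.metric):
                (r.value, r.obs_variance) for r in targets.itertuples()}
        values = np.array([tmap[nm][0] for nm in used])
        obs_var = np.array([tmap[nm][1] for nm in used])
        mean, var = w.emulator.predict(theta)
        im = implausibility(mean[used].to_numpy(), var[used].to_numpy(),
                            values[None, :], obs_var[None, :])
        inside &= im.max(axis=1) <= w.cutoff
    return inside


class SimulatorHarness:
    """Runs the microsimulation at parameter vectors and extracts the
    calibration-window response cells matching a target table."""

    def __init__(self, population: Population,
                 schedule: BaselineIncidenceSchedule,
                 life_table: LifeTable,
                 config: SimulationConfig,
                 targets: pd.DataFrame):
        self.population = population
        self.schedule = schedule
        self.life_table = life_table
        lo, hi = config.calibration_window
        # only simulate up to the calibration horizon during training runs
        self.config = SimulationConfig(
            start_year=config.start_year, end_year=hi,
            calibration_window=config.calibration_window,
            forecast_window=(hi, hi), seed=config.seed)
        self.targets = targets.reset_index(drop=True)
        self.names = [target_name(r.year, r.sex, r.age_group, r.metric)
                      for r in self.targets.itertuples()]

    def responses_from_result(self, result) -> pd.Series:
        table = compute_rates(result)
        idx = table.set_index(["year", "sex", "age_group", "metric"])["value"]
        key = list(zip(self.targets["year"], self.targets["sex"],
                       self.targets["age_group"], self.targets["metric"]))
        vals = idx.reindex(key).to_numpy()
        return pd.Series(vals, index=self.names)

    def run_one(self, params: ParameterVector, seed: int) -> pd.Series:
        cfg = SimulationConfig(
            start_year=self.config.start_year, end_year=self.config.end_year,
            calibration_window=self.config.calibration_window,
            forecast_window=self.config.forecast_window, seed=seed)
        result = simulate_population(self.population, params, self.schedule,
                                     self.life_table, cfg)
        return self.responses_from_result(result)

    def run_batch(self, design: pd.DataFrame, seeds: np.ndarray,
                  max_failures: float = 0.05) -> pd.DataFrame:
        rows, failures = [], 0
        vectors = frame_to_vectors(design)
        for vec, seed in zip(vectors, seeds):
            try:
                rows.append(self.run_one(vec, int(seed)))
            except Exception as exc:  # noqa: BLE001 - collected, rethrown below
                failures += 1
                rows.append(pd.Series(np.nan, index=self.names))
                warnings.warn(f"simulator run failed: {exc}", stacklevel=2)
        if failures > max_failures * len(design):
            raise RuntimeError(
                f"{failures}/{len(design)} simulator runs failed; aborting wave")
        return pd.DataFrame(rows).reset_index(drop=True)


def _run_seeds(seed: int, wave: int, n: int) -> np.ndarray:
    ss = np.random.SeedSequence([int(seed), int(wave)])
    return ss.generate_state(n) % (2 ** 31)


def run_waves(priors: dict[str, tuple[float, float]],
              harness: SimulatorHarness,
              targets: pd.DataFrame,
              config: HistoryMatchConfig | None = None):
    """The full calibration loop.

    Wave 1 trains on a Latin-hypercube design over the prior box and
    screens candidates drawn uniformly from it; later waves train on and
    screen candidates resampled from the previous wave's retained set.
    The retained proportion of the prior space is the running product of
    per-wave conditional retention; waves stop when it changes by less
    than ``rel_tol`` relatively between waves, or at ``max_waves``.
    Returns
    ``(final_vectors, waves)`` with exactly ``ensemble_size`` final
    vectors sampled uniformly (with replacement if needed) from the last
    retained set.
    """
    config = config or HistoryMatchConfig()
    rng = np.random.default_rng(config.seed)
    waves: list[WaveState] = []
    retained_pool: pd.DataFrame | None = None
    prev_prop = None
    cum_prop = 1.0

    for wave in range(1, config.max_waves + 1):
        if retained_pool is None:
            design = latin_hypercube(config.n_runs, priors,
                                     seed=int(rng.integers(2 ** 31)))
            candidates = pd.DataFrame(
                {k: rng.uniform(lo, hi, config.n_candidates)
                 for k, (lo, hi) in priors.items()})
        else:
            design = retained_pool.sample(
                n=config.n_runs, replace=len(retained_pool) < config.n_runs,
                random_state=int(rng.integers(2 ** 31))).reset_index(drop=True)
            candidates = retained_pool.sample(
                n=config.n_candidates, replace=True,
                random_state=int(rng.integers(2 ** 31))).reset_index(drop=True)

        responses = harness.run_batch(design, _run_seeds(config.seed, wave,
                                                         len(design)))
        ok = responses.notna().all(axis=1)
        training = TrainingSet(design=design[ok.to_numpy()].reset_index(drop=True),
                               responses=responses[ok.to_numpy()].reset_index(drop=True))
        model = fit_emulator(training, holdout_fraction=config.holdout_fraction,
                             backend=config.backend,
                             seed=int(rng.integers(2 ** 31)), box=priors)
        _, excluded = _active_targets(model, targets, config.diag_floor)
        retained, cond_prop, _ = screen(candidates, model, targets,
                                        cutoff=config.cutoff,
                                        diag_floor=config.diag_floor)
        cum_prop *= cond_prop
        store = retained
        if len(store) > config.max_retained_stored:
            store = store.sample(n=config.max_retained_stored,
                                 random_state=int(rng.integers(2 ** 31)))
        waves.append(WaveState(wave=wave, emulator=model,
                               retained=store.reset_index(drop=True),
                               proportion=cum_prop,
                               conditional_proportion=cond_prop,
                               cutoff=config.cutoff,
                               excluded_targets=excluded,
                               n_candidates=len(candidates)))
        retained_pool = waves[-1].retained
        if prev_prop is not None and prev_prop > 0:
            if abs(cum_prop - prev_prop) / prev_prop < config.rel_tol:
                break
        prev_prop = cum_prop

    final = retained_pool.sample(
        n=config.ensemble_size, replace=len(retained_pool) < config.ensemble_size,
        random_state=int(rng.integers(2 ** 31))).reset_index(drop=True)
    return final, waves


def forecast(final_vectors: pd.DataFrame,
             population: Population,
             schedule: BaselineIncidenceSchedule,
             life_table: LifeTable,
             config: SimulationConfig,
             weights: pd.Series | None = None,
             seed: int = 0,
             fresh_seeds: bool = True):
    """One full simulation to the horizon per ensemble vector.

    Returns ``(tables, summary, std_summary)``: the per-run rate tables,
    the per-cell median and 95% percentile band across runs, and the
    same for age-standardised event rates if ``weights`` is given.
    ``fresh_seeds`` re-randomises the simulation seed per vector so the
    ensemble spread includes Monte-Carlo variability; with it off (and
    identical vectors) the ensemble is degenerate.
    """
    seeds = (_run_seeds(seed, 0, len(final_vectors)) if fresh_seeds
             else np.full(len(final_vectors), seed))
    tables, std_tables = [], []
    for vec, run_seed in zip(frame_to_vectors(final_vectors), seeds):
        cfg = SimulationConfig(start_year=config.start_year,
                               end_year=config.end_year,
                               calibration_window=config.calibration_window,
                               forecast_window=config.forecast_window,
                               seed=int(run_seed))
        result = simulate_population(population, vec, schedule, life_table, cfg)
        table = compute_rates(result)
        tables.append(table)
        if weights is not None:
            std_tables.append(age_standardise(table, weights, metric="event"))
    summary = summarise_runs(tables)
    std_summary = (summarise_runs(std_tables, keys=("year", "sex", "metric"))
                   if weights is not None else None)
    return tables, summary, std_summary
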