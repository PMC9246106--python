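"""Aggregation of simulation runs into population rates.

Three headline outputs per (year, sex, age group):

* incidence — first MI events per 100,000 agents alive and MI-free at
  the start of the year;
* event rate — all MI events (first + recurrent) per 100,000 agents
  alive at the start of the year;
* prevalence — proportion of agents alive at the end of the year who
  have ever had an MI.

Denominator conventions (start-of-year for incidence/event, end-of-year
for prevalence) are fixed here because they shift rates visibly in
high-mortality strata.  Agents whose MI kills them within the year still
count in the incidence and event numerators.  Rates over ensembles of
runs are summarised by empirical percentiles with linear interpolation
between order statistics.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .engine import SimResult

__all__ = ["AGE_GROUPS", "age_group_of", "compute_rates", "age_standardise",
           "uncertainty_interval", "summarise_runs", "validate_against_holdout"]

AGE_GROUPS = ("55-64", "65-74", "75-84", "85+")
_EDGES = np.array([55, 65, 75, 85, 200])
METRICS = ("incidence", "event", "prevalence")


def age_group_of(age: np.ndarray) -> np.ndarray:
    """Map ages to output age-group labels; under-55s map to ''."""
    age = np.asarray(age)
    idx = np.searchsorted(_EDGES, age, side="right") - 1
    labels = np.array(["", *AGE_GROUPS], dtype=object)
    return labels[np.clip(idx, -1, len(AGE_GROUPS) - 1) + 1]


def compute_rates(result: SimResult, age_groups: Sequence[str] = AGE_GROUPS) -> pd.DataFrame:
    """Per (year, sex, age_group) rate table from one simulation run.

    Returns a long DataFrame with columns
    ``year, sex, age_group, metric, value, denominator``.  Cells with a
    zero denominator are flagged missing (NaN value), never reported as
    zero.  Incidence and event strata use start-of-year age; prevalence
    uses attained (end-of-year) age.
    """
    rows = []
    sexes = np.where(result.sex_male, "male", "female")
    for t, year in enumerate(result.years):
        g_start = age_group_of(result.age_start[:, t])
        g_end = age_group_of(result.age_start[:, t] + 1)
        alive0 = result.alive_start[:, t]
        prior0 = result.prior_start[:, t]
        alive1 = result.alive_end[:, t]
        prior1 = result.prior_end[:, t]
        events = result.first_mi[:, t] | result.recurrent_mi[:, t]
        for sex in ("male", "female"):
            s = sexes == sex
            for g in age_groups:
                m0 = s & (g_start == g)
                at_risk = m0 & alive0 & ~prior0
                n_alive0 = int((m0 & alive0).sum())
                n_at_risk = int(at_risk.sum())
                n_first = int((at_risk & result.first_mi[:, t]).sum())
                n_events = int((m0 & alive0 & events).sum())
                m1 = s & (g_end == g) & alive1
                n_alive1 = int(m1.sum())
                n_prev = int((m1 & prior1).sum())
                rows.append((int(year), sex, g, "incidence",
                             1e5 * n_first / n_at_risk if n_at_risk else np.nan,
                             n_at_risk))
                rows.append((int(year), sex, g, "event",
                             1e5 * n_events / n_alive0 if n_alive0 else np.nan,
                             n_alive0))
                rows.append((int(year), sex, g, "prevalence",
                             n_prev / n_alive1 if n_alive1 else np.nan,
                             n_alive1))
    return pd.DataFrame(rows, columns=["year", "sex", "age_group",
                                       "metric", "value", "denominator"])


def age_standardise(table: pd.DataFrame, weights: pd.Series,
                    metric: str = "event") -> pd.DataFrame:
    """Directly age-standardised rate per (year, sex).

    ``standardised = sum_g weight_g * rate(year, sex, g)``; weights must
    be non-negative and sum to 1.  A missing cell under a non-zero weight
    is an error (never silently dropped).
    """
    w = weights.astype(float)
    if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be non-negative and sum to 1")
    sub = table[table["metric"] == metric]
    out = []
    for (year, sex), grp in sub.groupby(["year", "sex"]):
        cell = grp.set_index("age_group")["value"]
        std = 0.0
        for g, wg in w.items():
            if wg == 0:
                continue
            if g not in cell.index or pd.isna(cell[g]):
                raise ValueError(f"missing {metric} cell for year={year}, "
                                 f"sex={sex}, age_group={g}")
            std += wg * cell[g]
        out.append((int(year), sex, metric, std))
    return pd.DataFrame(out, columns=["year", "sex", "metric", "value"])


def uncertainty_interval(values, level: float = 0.95) -> tuple[float, float]:
    """Empirical percentile interval across ensemble runs.

    Uses linear interpolation between order statistics (the same
    convention as ``numpy.quantile(method='linear')``); at the default
    level this is the 2.5th-97.5th percentile band.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values for a percentile interval")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)


def summarise_runs(tables: Sequence[pd.DataFrame], level: float = 0.95,
                   keys: Sequence[str] = ("year", "sex", "age_group", "metric")) -> pd.DataFrame:
    """Median and percentile interval per cell across an ensemble of rate
    tables (one per run)."""
    stacked = pd.concat(tables, keys=range(len(tables)), names=["run"]).reset_index(level=0)
    rows = []
    for key, grp in stacked.groupby(list(keys)):
        vals = grp["value"].dropna().to_numpy()
        if len(vals) < 2:
            med = lo = hi = np.nan if len(vals) == 0 else float(vals[0])
        else:
            med = float(np.median(vals))
            lo, hi = uncertainty_interval(vals, level)
        rows.append((*key, med, lo, hi))
    return pd.DataFrame(rows, columns=[*keys, "median", "lo95", "hi95"])


def validate_against_holdout(run_values: dict, holdout: pd.DataFrame,
                             base_level: float = 0.95) -> pd.DataFrame:
    """Interval-overlap validation against held-out external estimates.

    ``run_values`` maps a cell key (e.g. ``(sex, age_group)``) to the
    ensemble of per-run model values for that cell; ``holdout`` carries
    one row per cell with columns ``value, lo, hi`` (its own CI at
    ``base_level``) indexed by the same keys.  With ``m`` simultaneous
    cells, both intervals are recomputed at the Bonferroni-adjusted level
    ``1 - (1 - base_level)/m`` and overlap is reported per cell; overall
    validation passes iff every cell overlaps.
    """
    m = len(holdout)
    adj_level = 1.0 - (1.0 - base_level) / m
    z_base = stats.norm.ppf(0.5 + base_level / 2.0)
    z_adj = stats.norm.ppf(0.5 + adj_level / 2.0)
    rows = []
    for key, row in holdout.iterrows():
        model_lo, model_hi = uncertainty_interval(run_values[key], adj_level)
        # external CI widened from its reported base-level bounds via the
        # normal approximation
        se = (row["hi"] - row["lo"]) / (2.0 * z_base)
        ext_lo = row["value"] - z_adj * se
        ext_hi = row["value"] + z_adj * se
        overlap = (model_lo <= ext_hi) and (ext_lo <= model_hi)
        rows.append((key, model_lo, model_hi, ext_lo, ext_hi, overlap))
    out = pd.DataFrame(rows, columns=["cell", "model_lo", "model_hi",
                                      "ext_lo", "ext_hi", "overlap"])
    out.attrs["passed"] = bool(out["overlap"].all())
    out.attrs["adjusted_level"] = adj_level
    return out
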