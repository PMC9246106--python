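"""Calibrated parameters of the MI microsimulation.

A :class:`ParameterVector` collects the three classes of quantities the
calibration operates on: relative risks linking risk factors to MI
incidence, secular trends in risk-factor levels, and the secular trend in
30-day case fatality (a proxy for treatment improvement).  Priors are
independent uniforms on per-parameter ranges, supplied as a plain mapping
``{name: (lower, upper)}`` and serialisable to YAML/JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ParameterVector",
    "ReferenceLevels",
    "PARAM_NAMES",
    "default_priors",
    "load_priors",
    "save_priors",
    "vectors_to_frame",
    "frame_to_vectors",
]


@dataclass(frozen=True)
class ReferenceLevels:
    """Risk-factor levels at which all relative risks equal 1.

    The baseline incidence schedule is defined at these anchor values;
    an agent exactly at reference (non-smoker, non-diabetic, no prior MI)
    experiences the unscaled baseline hazard.
    """

    bmi_ref: float = 22.0    # kg/m^2
    sbp_ref: float = 115.0   # mmHg
    tchol_ref: float = 3.8   # mmol/L

    def __post_init__(self) -> None:
        if not (10 < self.bmi_ref < 50 and 70 < self.sbp_ref < 200 and 1 < self.tchol_ref < 10):
            raise ValueError("reference levels outside plausible physiological ranges")


@dataclass(frozen=True)
class ParameterVector:
    """One point in the calibrated parameter space.

    Relative risks are per stated increment above the reference level
    (5 kg/m^2 BMI, 10 mmHg SBP, 1 mmol/L total cholesterol); binary-factor
    relative risks apply multiplicatively when the factor is present.
    Trend parameters shift every agent's risk factors each simulated year;
    ``cf_trend`` is the proportional annual decline in 30-day case fatality.
    """

    rr_bmi: float = 1.25
    rr_sbp: float = 1.30
    rr_tchol: float = 1.30
    rr_smoking: float = 2.50
    rr_diabetes: float = 2.20
    rr_prior_mi: float = 3.00
    baseline_scale: float = 1.00
    trend_bmi_asymptote: float = 29.0   # kg/m^2
    trend_bmi_rate: float = 0.03        # fraction of gap closed per year
    trend_sbp_slope: float = -0.40      # mmHg / year
    trend_tchol_slope: float = -0.02    # mmol/L / year
    trend_smoking_quit: float = 0.03    # annual quit probability
    trend_diabetes_inc: float = 1.00    # scale on age-specific incidence
    cf_base: float = 0.30               # 30-day case fatality, age 70 male, base year
    cf_age_slope: float = 0.04          # log-odds per year of age
    cf_trend: float = 0.03              # proportional annual decline

    def __post_init__(self) -> None:
        for name in ("rr_bmi", "rr_sbp", "rr_tchol", "rr_smoking", "rr_diabetes",
                     "rr_prior_mi", "baseline_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("trend_smoking_quit", "cf_base"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.cf_trend < 1.0:
            raise ValueError("cf_trend must lie in [0, 1)")

    def to_series(self) -> pd.Series:
        return pd.Series(dataclasses.asdict(self), index=PARAM_NAMES, dtype=float)

    @classmethod
    def from_mapping(cls, values: Mapping[str, float]) -> "ParameterVector":
        return cls(**{k: float(values[k]) for k in PARAM_NAMES})

    def replace(self, **changes: float) -> "ParameterVector":
        return dataclasses.replace(self, **changes)


PARAM_NAMES: tuple[str, ...] = tuple(f.name for f in dataclasses.fields(ParameterVector))


def default_priors() -> dict[str, tuple[float, float]]:
    """Uniform prior ranges for every calibrated parameter.

    Ranges bracket values typical of cardiovascular risk epidemiology
    (e.g. smoking relative risks for MI of 2-3, 30-day case fatality near
    30% in the late 1990s) generously enough that the truth is interior.
    """
    return {
        "rr_bmi": (1.0, 1.6),
        "rr_sbp": (1.1, 1.6),
        "rr_tchol": (1.1, 1.7),
        "rr_smoking": (1.5, 4.0),
        "rr_diabetes": (1.5, 4.0),
        "rr_prior_mi": (1.5, 6.0),
        "baseline_scale": (0.3, 3.0),
        "trend_bmi_asymptote": (27.0, 32.0),
        "trend_bmi_rate": (0.0, 0.10),
        "trend_sbp_slope": (-1.0, 0.0),
        "trend_tchol_slope": (-0.06, 0.0),
        "trend_smoking_quit": (0.0, 0.08),
        "trend_diabetes_inc": (0.0, 2.0),
        "cf_base": (0.10, 0.50),
        "cf_age_slope": (0.0, 0.08),
        "cf_trend": (0.0, 0.06),
    }


def load_priors(path: str) -> dict[str, tuple[float, float]]:
    """Read priors from YAML or JSON: a list of ``{name, lower, upper}`` blocks
    or a mapping ``name -> [lower, upper]``."""
    with open(path) as fh:
        text = fh.read()
    data = json.loads(text) if path.endswith(".json") else yaml.safe_load(text)
    priors: dict[str, tuple[float, float]] = {}
    if isinstance(data, list):
        for block in data:
            priors[block["name"]] = (float(block["lower"]), float(block["upper"]))
    else:
        for name, rng in data.items():
            priors[name] = (float(rng[0]), float(rng[1]))
    _check_priors(priors)
    return priors


def save_priors(priors: Mapping[str, tuple[float, float]], path: str) -> None:
    blocks = [{"name": k, "lower": float(lo), "upper": float(hi)}
              for k, (lo, hi) in priors.items()]
    with open(path, "w") as fh:
        yaml.safe_dump(blocks, fh, sort_keys=False)


def _check_priors(priors: Mapping[str, tuple[float, float]]) -> None:
    for name, (lo, hi) in priors.items():
        if name not in PARAM_NAMES:
            raise KeyError(f"unknown parameter {name!r}")
        if not np.isfinite(lo) or not np.isfinite(hi) or hi < lo:
            raise ValueError(f"invalid range for {name}: ({lo}, {hi})")


def vectors_to_frame(vectors: Iterable[ParameterVector]) -> pd.DataFrame:
    """Stack parameter vectors into a DataFrame, one row per vector."""
    return pd.DataFrame([v.to_series() for v in vectors]).reset_index(drop=True)


def frame_to_vectors(frame: pd.DataFrame, defaults: ParameterVector | None = None) -> list[ParameterVector]:
    """Rows of a DataFrame as parameter vectors; columns absent from the
    frame fall back to ``defaults`` (the class defaults if None)."""
    base = (defaults or ParameterVector()).to_series()
    out = []
    for _, row in frame.iterrows():
        merged = base.copy()
        merged[row.index.intersection(PARAM_NAMES)] = row[row.index.intersection(PARAM_NAMES)]
        out.append(ParameterVector.from_mapping(merged))
    return out
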