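"""Synthetic agent populations and exogenous demographic inputs.

The simulated population is a closed cohort: a fixed sample of adults
spanning ages 18-100 at the base year, with no births or migration.
Younger adults are included so that everyone who reaches the over-55
output window by the simulation horizon already exists at baseline.

Continuous risk factors (BMI, systolic blood pressure, total cholesterol)
are drawn from truncated normal distributions specified per sex and age
band; binary factors (smoking, diabetes, prior MI) are Bernoulli with
per-stratum prevalences.  Non-MI mortality comes from an exogenous life
table of annual death probabilities by sex, age and calendar year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Agent",
    "Population",
    "LifeTable",
    "PLAUSIBLE_RANGES",
    "AGE_RANGE",
    "sample_initial_population",
    "generate_life_table",
    "default_demography",
    "default_risk_spec",
    "default_life_table",
    "default_standard_weights",
]

# Hard truncation limits for generated continuous risk factors.
PLAUSIBLE_RANGES: dict[str, tuple[float, float]] = {
    "bmi": (14.0, 60.0),
    "sbp": (80.0, 230.0),
    "tchol": (2.0, 12.0),
}

AGE_RANGE = (18, 100)  # ages present at baseline

POPULATION_COLUMNS = ["id", "sex", "age", "bmi", "sbp", "tchol",
                      "smoker", "diabetic", "prior_mi", "year_first_mi"]


@dataclass
class Agent:
    """One simulated person's state."""

    id: int
    sex: str                      # "male" | "female"
    age: int                      # completed years
    bmi: float                    # kg/m^2
    sbp: float                    # mmHg, systolic
    tchol: float                  # mmol/L, total cholesterol
    smoker: bool
    diabetic: bool
    prior_mi: bool = False
    year_first_mi: int | None = None
    alive: bool = True
    cause_of_death: str = "none"  # "none" | "mi" | "other"

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.age < 0:
            raise ValueError("age must be non-negative")
        if min(self.bmi, self.sbp, self.tchol) <= 0:
            raise ValueError("continuous risk factors must be positive")
        if self.prior_mi != (self.year_first_mi is not None):
            raise ValueError("prior_mi must be set iff year_first_mi is set")
        if (self.cause_of_death != "none") == self.alive:
            raise ValueError("cause_of_death must be set iff agent is dead")


class Population:
    """A collection of agents at a common base year, column-oriented.

    Backed by a DataFrame with one row per agent; ``agents()`` yields
    :class:`Agent` views for scalar-level work.  Ids must be unique; an
    empty population is permitted.
    """

    def __init__(self, frame: pd.DataFrame, base_year: int = 1998, seed: int | None = None):
        frame = frame.reset_index(drop=True)
        missing = [c for c in POPULATION_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"population frame missing columns: {missing}")
        if frame["id"].duplicated().any():
            raise ValueError("agent ids must be unique")
        self.frame = frame
        self.base_year = int(base_year)
        self.seed = seed

    def __len__(self) -> int:
        return len(self.frame)

    def agents(self):
        for row in self.frame.itertuples(index=False):
            yfm = None if pd.isna(row.year_first_mi) else int(row.year_first_mi)
            yield Agent(id=int(row.id), sex=row.sex, age=int(row.age),
                        bmi=float(row.bmi), sbp=float(row.sbp), tchol=float(row.tchol),
                        smoker=bool(row.smoker), diabetic=bool(row.diabetic),
                        prior_mi=bool(row.prior_mi), year_first_mi=yfm)

    def to_csv(self, path: str) -> None:
        out = self.frame.copy()
        for col in ("smoker", "diabetic", "prior_mi"):
            out[col] = out[col].astype(int)
        out["year_first_mi"] = out["year_first_mi"].astype("Int64")
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str, base_year: int = 1998) -> "Population":
        frame = pd.read_csv(path)
        for col in ("smoker", "diabetic", "prior_mi"):
            frame[col] = frame[col].astype(bool)
        if "year_first_mi" in frame:
            frame["year_first_mi"] = frame["year_first_mi"].astype("Int64")
        return cls(frame, base_year=base_year)


@dataclass
class LifeTable:
    """Annual probability of death from non-MI causes by sex, age, year.

    Stored dense: ``q[sex][age - age_min, year - year_min]``.  Lookups
    outside the covered grid raise rather than extrapolate.
    """

    ages: np.ndarray
    years: np.ndarray
    q: dict[str, np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        for sex, arr in self.q.items():
            if arr.shape != (len(self.ages), len(self.years)):
                raise ValueError(f"life-table block for {sex} has wrong shape")
            if (arr < 0).any() or (arr > 1).any():
                raise ValueError("life-table probabilities must lie in [0, 1]")

    def lookup(self, sex: str, age: int, year: int) -> float:
        return float(self.q[sex][self._age_idx(age), self._year_idx(year)])

    def lookup_array(self, sex_male: np.ndarray, age: np.ndarray, year: int) -> np.ndarray:
        """Vectorised lookup for one calendar year; ``sex_male`` boolean."""
        ai = self._age_idx_array(age)
        yi = self._year_idx(year)
        return np.where(sex_male, self.q["male"][ai, yi], self.q["female"][ai, yi])

    def _age_idx(self, age: int) -> int:
        if not self.ages[0] <= age <= self.ages[-1]:
            raise KeyError(f"age {age} outside life table range "
                           f"[{self.ages[0]}, {self.ages[-1]}]")
        return int(age - self.ages[0])

    def _age_idx_array(self, age: np.ndarray) -> np.ndarray:
        if age.size and (age.min() < self.ages[0] or age.max() > self.ages[-1]):
            bad = int(age.max() if age.max() > self.ages[-1] else age.min())
            raise KeyError(f"age {bad} outside life table range")
        return (age - self.ages[0]).astype(np.intp)

    def _year_idx(self, year: int) -> int:
        if not self.years[0] <= year <= self.years[-1]:
            raise KeyError(f"year {year} outside life table range "
                           f"[{self.years[0]}, {self.years[-1]}]")
        return int(year - self.years[0])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sex, arr in self.q.items():
            a, y = np.meshgrid(self.ages, self.years, indexing="ij")
            rows.append(pd.DataFrame({"sex": sex, "age": a.ravel(),
                                      "year": y.ravel(), "q_other": arr.ravel()}))
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str) -> "LifeTable":
        frame = pd.read_csv(path)
        ages = np.sort(frame["age"].unique())
        years = np.sort(frame["year"].unique())
        q = {}
        for sex, grp in frame.groupby("sex"):
            pivot = grp.pivot(index="age", columns="year", values="q_other")
            pivot = pivot.reindex(index=ages, columns=years)
            if pivot.isna().any().any():
                raise ValueError(f"life-table CSV has holes for sex={sex}")
            q[sex] = pivot.to_numpy(dtype=float)
        return cls(ages=ages, years=years, q=q)


# ---------------------------------------------------------------------------
# Generators

def default_demography() -> dict[str, list[tuple[int, int, float]]]:
    """Age-band weights per sex approximating the adult age structure of a
    late-1990s western European population (synthetic stand-in; weights per
    sex sum to 1)."""
    male = [(18, 24, 0.115), (25, 34, 0.20), (35, 44, 0.18), (45, 54, 0.165),
            (55, 64, 0.135), (65, 74, 0.115), (75, 84, 0.07), (85, 100, 0.02)]
    female = [(18, 24, 0.105), (25, 34, 0.19), (35, 44, 0.175), (45, 54, 0.16),
              (55, 64, 0.135), (65, 74, 0.12), (75, 84, 0.08), (85, 100, 0.035)]
    return {"male": male, "female": female}


def default_risk_spec() -> dict[tuple[str, tuple[int, int]], dict[str, float]]:
    """Per sex and age band: means/SDs of continuous factors and
    prevalences of binary factors at the 1998 baseline.

    Levels follow the broad age gradients seen in national health
    examination surveys of the period: SBP and cholesterol rising with
    age, smoking declining, diabetes rising, prior-MI prevalence reaching
    ~20% in the oldest men and about half that in women.
    """
    bands = [(18, 24), (25, 34), (35, 44), (45, 54), (55, 64), (65, 74), (75, 84), (85, 100)]
    sbp_means = [122, 124, 127, 131, 137, 143, 148, 150]
    tch_means = [4.6, 5.0, 5.4, 5.8, 6.0, 6.1, 6.0, 5.8]
    bmi_means = [24.0, 25.5, 26.5, 27.2, 27.5, 27.3, 26.6, 25.5]
    smoke = [0.32, 0.32, 0.30, 0.28, 0.26, 0.18, 0.12, 0.08]
    diab = [0.005, 0.01, 0.02, 0.04, 0.07, 0.10, 0.12, 0.12]
    prior_mi_male = [0.0, 0.0, 0.005, 0.02, 0.05, 0.10, 0.15, 0.20]
    spec: dict[tuple[str, tuple[int, int]], dict[str, float]] = {}
    for i, band in enumerate(bands):
        for sex in ("male", "female"):
            f = sex == "female"
            spec[(sex, band)] = {
                "bmi_mean": bmi_means[i] - (0.3 if f else 0.0), "bmi_sd": 4.5,
                "sbp_mean": sbp_means[i] - (4.0 if f else 0.0), "sbp_sd": 15.0,
                "tchol_mean": tch_means[i] + (0.1 if f else 0.0), "tchol_sd": 1.1,
                "smoker_prev": smoke[i] - (0.02 if f else 0.0),
                "diabetic_prev": diab[i] * (0.8 if f else 1.0),
                "prior_mi_prev": prior_mi_male[i] * (0.5 if f else 1.0),
            }
    return spec


def sample_initial_population(n: int,
                              base_year: int = 1998,
                              demography: dict | None = None,
                              risk_spec: dict | None = None,
                              seed: int = 0) -> Population:
    """Draw a baseline population of ``n`` agents.

    Ages are drawn from the banded ``demography`` (uniform within band),
    continuous risk factors from truncated normals per (sex, age band),
    and binary factors from per-stratum Bernoullis.  Agents initialised
    with a prior MI get ``year_first_mi`` set to a year before baseline.
    Deterministic given ``seed``.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    demography = demography or default_demography()
    risk_spec = risk_spec or default_risk_spec()
    rng = np.random.default_rng(seed)

    if n == 0:
        frame = pd.DataFrame(columns=POPULATION_COLUMNS)
        frame = frame.astype({"id": int, "age": int, "bmi": float, "sbp": float,
                              "tchol": float, "smoker": bool, "diabetic": bool,
                              "prior_mi": bool})
        return Population(frame, base_year=base_year, seed=seed)

    sexes = list(demography)
    sex_weights = np.array([sum(w for _, _, w in demography[s]) for s in sexes], float)
    sex_weights /= sex_weights.sum()
    sex_idx = rng.choice(len(sexes), size=n, p=sex_weights)

    age = np.empty(n, dtype=int)
    sex_arr = np.array([sexes[i] for i in sex_idx], dtype=object)
    for si, sex in enumerate(sexes):
        mask = sex_idx == si
        bands = demography[sex]
        w = np.array([b[2] for b in bands], float)
        w /= w.sum()
        band_idx = rng.choice(len(bands), size=mask.sum(), p=w)
        lo = np.array([bands[i][0] for i in band_idx])
        hi = np.array([bands[i][1] for i in band_idx])
        age[mask] = rng.integers(lo, hi + 1)

    bmi = np.empty(n)
    sbp = np.empty(n)
    tchol = np.empty(n)
    smoker = np.zeros(n, bool)
    diabetic = np.zeros(n, bool)
    prior_mi = np.zeros(n, bool)

    strata = pd.DataFrame({"sex": sex_arr, "age": age})
    for (sex, band), spec in risk_spec.items():
        mask = ((strata["sex"] == sex) & (age >= band[0]) & (age <= band[1])).to_numpy()
        m = mask.sum()
        if m == 0:
            continue
        for col, arr in (("bmi", bmi), ("sbp", sbp), ("tchol", tchol)):
            lo_t, hi_t = PLAUSIBLE_RANGES[col]
            mu, sd = spec[f"{col}_mean"], spec[f"{col}_sd"]
            a, b = (lo_t - mu) / sd, (hi_t - mu) / sd
            arr[mask] = stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=m,
                                            random_state=rng)
        smoker[mask] = rng.random(m) < spec["smoker_prev"]
        diabetic[mask] = rng.random(m) < spec["diabetic_prev"]
        prior_mi[mask] = rng.random(m) < spec["prior_mi_prev"]
        strata.loc[mask, "sex"] = "__done__"  # mark covered

    uncovered = strata["sex"] != "__done__"
    if uncovered.any():
        i = int(np.flatnonzero(uncovered.to_numpy())[0])
        raise KeyError(f"risk_spec missing age band for sex={sex_arr[i]}, age={age[i]}")

    year_first_mi = pd.array([base_year - int(rng.integers(1, 11)) if p else pd.NA
                              for p in prior_mi], dtype="Int64")
    frame = pd.DataFrame({
        "id": np.arange(n), "sex": sex_arr, "age": age,
        "bmi": bmi, "sbp": sbp, "tchol": tchol,
        "smoker": smoker, "diabetic": diabetic, "prior_mi": prior_mi,
        "year_first_mi": year_first_mi,
    })
    return Population(frame, base_year=base_year, seed=seed)


def generate_life_table(schedule: dict[str, np.ndarray] | None = None,
                        improvement: float = 0.01,
                        years: tuple[int, int] = (1998, 2035),
                        ages: tuple[int, int] = (0, 150)) -> LifeTable:
    """Build a life table from base-year probabilities and a constant
    annual improvement rate.

    ``q(sex, age, year) = q_base(sex, age) * (1 - improvement)^(year - y0)``,
    clamped to [0, 1].  The default base schedule is Gompertz-like in age
    with a small background floor, slightly higher for men.
    """
    if improvement < 0:
        raise ValueError("improvement rate must be non-negative")
    age_arr = np.arange(ages[0], ages[1] + 1)
    year_arr = np.arange(years[0], years[1] + 1)
    if schedule is None:
        base = 5e-5 * np.exp(0.095 * age_arr) + 5e-4
        schedule = {"male": np.minimum(1.2 * base, 1.0),
                    "female": np.minimum(0.85 * base, 1.0)}
    factor = (1.0 - improvement) ** (year_arr - years[0])
    q = {}
    for sex, base_q in schedule.items():
        base_q = np.asarray(base_q, dtype=float)
        if base_q.shape != age_arr.shape:
            raise ValueError("schedule must give one base probability per age")
        if (base_q < 0).any() or (base_q > 1).any():
            raise ValueError("base probabilities must lie in [0, 1]")
        q[sex] = np.clip(base_q[:, None] * factor[None, :], 0.0, 1.0)
    return LifeTable(ages=age_arr, years=year_arr, q=q)


def default_life_table(years: tuple[int, int] = (1998, 2035)) -> LifeTable:
    return generate_life_table(years=years)


def default_standard_weights() -> pd.Series:
    """Reference over-55 age structure for age standardisation (synthetic
    stand-in for a 2018 national structure; weights sum to 1)."""
    return pd.Series({"55-64": 0.39, "65-74": 0.33, "75-84": 0.20, "85+": 0.08},
                     name="weight")
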