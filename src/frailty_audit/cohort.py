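"""Synthetic cohort generator with the statistical structure the frailty
audit assumes: age-graded correlated deficits, sex/height/BMI-dependent
performance measures, right-skewed survey weights, discrete-time mortality
follow-up of at most 13 years, and optional MCAR / age-dependent missingness.

A single latent frailty propensity ``Z`` (a standardized monotone function
of age plus standard-normal noise) drives the correlation among deficits,
ordinal symptom scales and performance measures.  ``frailty_loading`` scales
every loading on ``Z``; at 0 all health variables are mutually independent.
The generator is fully deterministic given ``CohortSpec.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .variables import (
    BINARY_INPUTS,
    BURDEN_DEFICITS,
    ORDINAL_INPUTS,
    RAW_INPUTS,
    variable_catalogue,
)

MAX_FOLLOWUP_YEARS = 13

#: columns that are never masked by inject_missingness
PROTECTED_COLUMNS = (
    "id", "age", "sex", "race_ethnicity", "education", "income_pc",
    "wealth_pc", "survey_weight", "latent_frailty", "eligible_65",
    "eligible_70", "followup_time", "died",
)


def _default_intercepts(max_followup: int) -> tuple[float, ...]:
    # baseline yearly death log-odds, rising gently with follow-up year
    return tuple(-3.3 + 0.07 * (t - 1) for t in range(1, max_followup + 1))


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters for one synthetic cohort."""

    n_participants: int = 4000
    seed: int = 0
    age_range: tuple[float, float] = (50.0, 95.0)
    frailty_loading: float = 1.0
    hazard_intercepts: Optional[Sequence[float]] = None
    hazard_betas: Mapping[str, float] = field(
        default_factory=lambda: {"latent_frailty": 0.9}
    )
    max_followup: int = MAX_FOLLOWUP_YEARS
    missing_rate: float = 0.0
    weight_dispersion: float = 0.5

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not isinstance(self.seed, (int, np.integer)):
            raise TypeError("seed must be an integer")
        if not (1 <= self.max_followup <= MAX_FOLLOWUP_YEARS):
            raise ValueError(f"max_followup must be in 1..{MAX_FOLLOWUP_YEARS}")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.weight_dispersion < 0:
            raise ValueError("weight_dispersion must be >= 0")

    @property
    def intercepts(self) -> np.ndarray:
        if self.hazard_intercepts is None:
            return np.asarray(_default_intercepts(self.max_followup), dtype=float)
        arr = np.asarray(self.hazard_intercepts, dtype=float)
        if arr.ndim == 0:
            arr = np.repeat(arr, self.max_followup)
        if arr.shape != (self.max_followup,):
            raise ValueError("hazard_intercepts must have one entry per follow-up year")
        return arr


# per-variable generative parameters: (baseline logit, loading on Z)
_BINARY_PARAMS: dict[str, tuple[float, float]] = {
    "dizziness": (-2.6, 1.0),
    "difficulty_lifting": (-2.0, 1.2),
    "difficulty_climbing": (-1.9, 1.2),
    "weight_loss": (-2.4, 1.0),
    "underweight": (-3.0, 0.8),
    "cognitive_impairment": (-2.6, 1.1),
    "memory_problem": (-2.2, 1.0),
    "poor_hearing": (-2.0, 0.9),
    "poor_eyesight": (-2.2, 0.9),
    "effort_everything": (-2.0, 1.1),
    "cannot_get_going": (-2.2, 1.1),
    "proxy_cognition_poor": (-2.8, 1.0),
}
for _i, _name in enumerate(BURDEN_DEFICITS):
    _BINARY_PARAMS[_name] = (-2.8 + 0.05 * _i, 0.8 + 0.04 * (_i % 7))

# standard-normal cutpoints per ordinal category count
_ORDINAL_CUTS = {
    3: np.array([0.3, 1.4]),
    4: np.array([0.0, 0.9, 1.7]),
    5: np.array([-0.2, 0.6, 1.3, 2.0]),
}


def _numeric_values(table: pd.DataFrame, name: str) -> np.ndarray:
    """Numeric representation of a column for use in linear predictors."""
    if name == "sex":
        return (table["sex"].to_numpy() == "female").astype(float)
    col = table[name]
    if col.dtype == object:
        raise ValueError(f"column {name!r} is not numeric")
    return col.to_numpy(dtype=float)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a baseline cohort table (one row per participant), including
    survival follow-up drawn from the discrete-time hazard in ``spec``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants
    load = spec.frailty_loading

    age_lo, age_hi = spec.age_range
    age = rng.uniform(age_lo, age_hi, n)
    # standardized monotone function of age plus standard-normal noise
    age_sd = max((age_hi - age_lo) / np.sqrt(12.0), 1e-9)
    z_age = (age - (age_lo + age_hi) / 2.0) / age_sd
    z = (z_age + rng.standard_normal(n)) / np.sqrt(2.0)

    sex = np.where(rng.random(n) < 0.54, "female", "male")
    female = (sex == "female").astype(float)
    race = rng.choice(
        ["white", "black", "hispanic", "other"], size=n, p=[0.70, 0.15, 0.10, 0.05]
    )
    education = np.clip(np.round(rng.normal(12.5, 3.0, n)), 0, 17)
    income_pc = np.round(np.exp(rng.normal(9.8, 0.9, n)), 2)
    wealth_pc = np.round(np.exp(rng.normal(11.0, 1.4, n)), 2)

    if spec.weight_dispersion > 0:
        shape = 1.0 / spec.weight_dispersion**2
        weights = rng.gamma(shape, scale=1.0 / shape, size=n)
        weights = np.maximum(weights, 1e-6)
    else:
        weights = np.ones(n)

    table = pd.DataFrame(
        {
            "id": np.arange(n),
            "age": np.round(age, 2),
            "sex": sex,
            "race_ethnicity": race,
            "education": education,
            "income_pc": income_pc,
            "wealth_pc": wealth_pc,
            "survey_weight": weights,
            "latent_frailty": z,
        }
    )

    for name in BINARY_INPUTS + BURDEN_DEFICITS:
        a, b = _BINARY_PARAMS[name]
        table[name] = (rng.random(n) < expit(a + b * load * z)).astype(int)

    for name, k in ORDINAL_INPUTS.items():
        latent = 0.8 * load * z + rng.standard_normal(n)
        table[name] = 1 + np.searchsorted(_ORDINAL_CUTS[k], latent).astype(int)
        # searchsorted over cuts yields ranks 1..k

    height = np.where(
        female, rng.normal(1.62, 0.065, n), rng.normal(1.76, 0.07, n)
    )
    height = np.clip(height, 1.30, 2.10)
    bmi_latent = np.clip(rng.normal(27.5, 4.5, n), 16.0, 50.0)
    weight_kg = bmi_latent * height**2

    cognition = np.clip(25.0 - 3.0 * load * z + rng.normal(0.0, 3.0, n), 0.0, 35.0)
    activity = np.exp(rng.normal(2.2 - 0.35 * load * z, 0.6))
    walk_time = np.exp(
        0.95 + 0.18 * load * z + 0.06 * female - 0.5 * (height - 1.70)
        + rng.normal(0.0, 0.22, n)
    )
    grip = (
        np.where(female, 26.0, 42.0)
        + 25.0 * (height - 1.70)
        + 0.15 * (bmi_latent - 27.5)
        - 3.5 * load * z
        + rng.normal(0.0, 4.5, n)
    )
    grip = np.clip(grip, 2.0, None)

    table["cognition_score"] = np.round(cognition, 2)
    table["activity_score"] = np.round(activity, 3)
    table["walk_time_8ft"] = np.round(walk_time, 3)
    table["grip_strength"] = np.round(grip, 2)
    table["height"] = np.round(height, 3)
    table["weight_kg"] = np.round(weight_kg, 2)

    table["eligible_65"] = (table["age"] >= 65).astype(int)
    table["eligible_70"] = (table["age"] >= 70).astype(int)

    table = generate_survival(table, spec, rng=rng)
    return table


def generate_survival(
    table: pd.DataFrame, spec: CohortSpec, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Draw yearly death events from logistic(alpha_t + beta'x) and attach
    ``followup_time`` (first death year, or max_followup if censored) and
    ``died`` columns.  Deterministic given the spec seed."""
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1_000_003)
    n = len(table)
    alphas = spec.intercepts

    lin = np.zeros(n)
    for name, beta in spec.hazard_betas.items():
        if name not in table.columns and name != "sex":
            raise KeyError(f"hazard_betas references unknown column {name!r}")
        lin += beta * _numeric_values(table, name)

    followup = np.full(n, spec.max_followup, dtype=int)
    died = np.zeros(n, dtype=int)
    alive = np.ones(n, dtype=bool)
    u = rng.random((spec.max_followup, n))
    for t in range(1, spec.max_followup + 1):
        hazard = expit(alphas[t - 1] + lin)
        dies_now = alive & (u[t - 1] < hazard)
        followup[dies_now] = t
        died[dies_now] = 1
        alive &= ~dies_now

    out = table.copy()
    out["followup_time"] = followup
    out["died"] = died
    return out


def inject_missingness(
    table: pd.DataFrame,
    rate: float,
    mechanism: str = "MCAR",
    seed: int = 0,
    columns: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Mask a fraction of deficit / ordinal / continuous cells.

    ``MCAR`` masks cells uniformly at random at the stated rate; ``MAR-age``
    scales each participant's masking probability by their age percentile
    (mean rate preserved), so older participants have more missing cells.
    Demographics, weights and survival columns are never masked.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must lie in [0, 1)")
    if mechanism not in {"MCAR", "MAR-age"}:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    if rate == 0.0:
        return table.copy()

    if columns is None:
        columns = [c for c in RAW_INPUTS if c in table.columns]
    bad = set(columns) & set(PROTECTED_COLUMNS)
    if bad:
        raise ValueError(f"cannot mask protected columns: {sorted(bad)}")

    rng = np.random.default_rng(seed)
    n = len(table)
    if mechanism == "MCAR":
        p_row = np.full(n, rate)
    else:
        ranks = table["age"].rank(method="average").to_numpy() / n
        p_row = np.clip(2.0 * rate * ranks, 0.0, 0.95)

    out = table.copy()
    for col in columns:
        mask = rng.random(n) < p_row
        out[col] = out[col].astype(float)
        out.loc[mask, col] = np.nan
    return out


def simulate(spec: CohortSpec) -> pd.DataFrame:
    """Convenience wrapper: cohort + survival + missingness per the spec."""
    table = generate_cohort(spec)
    if spec.missing_rate > 0:
        table = inject_missingness(
            table, spec.missing_rate, mechanism="MAR-age", seed=spec.seed + 17
        )
    return table


# ---------------------------------------------------------------------------
# CSV round-trip with a sidecar JSON schema
# ---------------------------------------------------------------------------

def _schema(table: pd.DataFrame) -> dict:
    cat = variable_catalogue()
    schema: dict[str, dict] = {}
    for col in table.columns:
        if col in cat:
            v = cat[col]
            entry: dict = {"kind": v.kind}
            if v.kind == "ordinal":
                entry["categories"] = v.n_categories
        elif col in ("sex", "race_ethnicity"):
            entry = {"kind": "categorical",
                     "categories": sorted(table[col].dropna().unique().tolist())}
        elif col in ("followup_time", "died", "eligible_65", "eligible_70", "id"):
            entry = {"kind": "integer"}
        else:
            entry = {"kind": "continuous"}
        units = {"age": "years", "walk_time_8ft": "seconds",
                 "grip_strength": "kg", "height": "m", "weight_kg": "kg",
                 "education": "years", "followup_time": "years"}
        if col in units:
            entry["units"] = units[col]
        schema[col] = entry
    return schema


def write_cohort(table: pd.DataFrame, path) -> None:
    """Write a cohort as CSV (missing cells empty) plus ``<path>.schema.json``."""
    path = Path(path)
    table.to_csv(path, index=False)
    with open(str(path) + ".schema.json", "w") as fh:
        json.dump(_schema(table), fh, indent=1)


def read_cohort(path) -> pd.DataFrame:
    path = Path(path)
    table = pd.read_csv(path)
    return table
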