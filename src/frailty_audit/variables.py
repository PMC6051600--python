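"""Variable catalogue and frailty-model definitions.

Three deficit-accumulation frailty models are audited by this package:

* **Functional Domains (FD)** — four [0, 1] domain scores (physical,
  nutritive/weight-loss, cognitive, sensory) summed to an index in [0, 4];
  frail iff index >= 2.  Age eligibility 65+.
* **Burden** — 24 equally weighted items, each scaled to [0, 1], summed and
  divided by the item count, giving an index in [0, 1]; frail iff
  index >= 0.2.  Age eligibility 70+.
* **Biologic Syndrome (BS)** — five [0, 1] criteria (weight loss, exhaustion,
  low energy expenditure, slowness, weakness) summed to [0, 5]; frail iff
  index >= 3.  Age eligibility 65+.  The weight-loss domain is shared with
  the FD model, so eight distinct FD/BS domains exist; the Burden cognition
  domain brings the total to nine derived domain variables.

The module also fixes the default 72-variable menu used by the index miner:
44 raw inputs, 19 intermediate derived variables and the 9 domain variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import yaml

# ---------------------------------------------------------------------------
# Raw variable menu (44 variables)
# ---------------------------------------------------------------------------

#: binary symptom / history indicators (0/1)
BINARY_INPUTS = [
    "dizziness",
    "difficulty_lifting",
    "difficulty_climbing",
    "weight_loss",
    "underweight",
    "cognitive_impairment",
    "memory_problem",
    "poor_hearing",
    "poor_eyesight",
    "effort_everything",
    "cannot_get_going",
    "proxy_cognition_poor",
]

#: continuous performance / anthropometric measures
CONTINUOUS_INPUTS = [
    "cognition_score",   # performance-based cognition score (points)
    "activity_score",    # summary score of physical activity frequency
    "walk_time_8ft",     # seconds to walk 8 feet
    "grip_strength",     # kg
    "height",            # m
    "weight_kg",         # kg
]

#: generic binary deficits feeding the Burden scale (plus spares for mining)
BURDEN_DEFICITS = [f"d{i:02d}" for i in range(1, 22)]  # d01..d21

#: ordinal symptom scales with their category counts
ORDINAL_INPUTS = {"o1": 5, "o2": 5, "o3": 4, "o4": 3, "o5": 5}

RAW_INPUTS = BINARY_INPUTS + CONTINUOUS_INPUTS + BURDEN_DEFICITS + list(ORDINAL_INPUTS)

# ---------------------------------------------------------------------------
# Derived intermediates (19 variables)
# ---------------------------------------------------------------------------

SCALED_ORDINALS = [f"scaled__{o}" for o in ORDINAL_INPUTS]

DERIVED_VARIABLES = SCALED_ORDINALS + [
    "walk_time_15ft",        # walk_time_8ft * 15/8
    "bmi",                   # weight_kg / height^2
    "flag__low_cognition",   # lowest quintile of cognition_score
    "flag__low_activity",    # lowest quintile of activity_score, by sex
    "flag__slow_walk",       # slowest 20% of walk_time_15ft, by sex x height
    "flag__weak_grip",       # weakest 20% of grip_strength, by sex x BMI
    "sum__physical",         # raw (pre-censoring) domain sums
    "sum__weight_loss",
    "sum__cognitive",
    "sum__sensory",
    "sum__exhaustion",
    "sum__burden_cognition",
    "height_group",          # sex-specific median split of height
    "bmi_group",             # sex-specific BMI quartile
]

# ---------------------------------------------------------------------------
# Domain variables (9)
# ---------------------------------------------------------------------------

DOMAIN_NAMES = [
    "physical",
    "weight_loss",
    "cognitive",
    "sensory",
    "exhaustion",
    "low_energy",
    "slowness",
    "weakness",
    "burden_cognition",
]

DOMAIN_COLUMNS = [f"domain__{d}" for d in DOMAIN_NAMES]


def default_variable_pool() -> list[str]:
    """The 72-name menu for alternative-index mining: 44 raw inputs,
    19 derived variables and 9 domain variables."""
    pool = RAW_INPUTS + DERIVED_VARIABLES + DOMAIN_COLUMNS
    assert len(pool) == 72, len(pool)
    return pool


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariableSpec:
    """Metadata for one input variable."""

    name: str
    kind: str                                # binary | ordinal | continuous
    n_categories: Optional[int] = None       # ordinal only
    model_membership: tuple[str, ...] = ()
    domain: Optional[str] = None
    stratifiers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in {"binary", "ordinal", "continuous"}:
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind == "ordinal" and (self.n_categories is None or self.n_categories < 2):
            raise ValueError("ordinal variables need n_categories >= 2")


@dataclass(frozen=True)
class DomainDef:
    """Recipe for one [0, 1] domain variable.

    ``censored_sum`` domains add binary indicators and cap the sum at 1;
    ``quantile_flag`` domains flag the stated extreme tail of a continuous
    measure within strata.
    """

    name: str
    method: str                      # censored_sum | quantile_flag
    inputs: tuple[str, ...]          # columns consumed by the recipe
    design: tuple[str, ...]          # columns for the bias (OLS) regression
    q: float = 0.2
    direction: str = "lowest"        # lowest | highest
    stratifiers: tuple[str, ...] = ()

    @property
    def column(self) -> str:
        return f"domain__{self.name}"


DOMAIN_DEFS: dict[str, DomainDef] = {
    d.name: d
    for d in [
        DomainDef("physical", "censored_sum",
                  ("dizziness", "difficulty_lifting", "difficulty_climbing"),
                  ("dizziness", "difficulty_lifting", "difficulty_climbing")),
        DomainDef("weight_loss", "censored_sum",
                  ("weight_loss", "underweight"),
                  ("weight_loss", "underweight")),
        DomainDef("cognitive", "censored_sum",
                  ("cognitive_impairment", "memory_problem"),
                  ("cognitive_impairment", "memory_problem")),
        DomainDef("sensory", "censored_sum",
                  ("poor_hearing", "poor_eyesight"),
                  ("poor_hearing", "poor_eyesight")),
        DomainDef("exhaustion", "censored_sum",
                  ("effort_everything", "cannot_get_going"),
                  ("effort_everything", "cannot_get_going")),
        DomainDef("low_energy", "quantile_flag",
                  ("activity_score",),
                  ("activity_score", "sex"),
                  q=0.2, direction="lowest", stratifiers=("sex",)),
        DomainDef("slowness", "quantile_flag",
                  ("walk_time_8ft",),
                  ("walk_time_8ft", "sex", "height"),
                  q=0.2, direction="highest", stratifiers=("sex", "height_group")),
        DomainDef("weakness", "quantile_flag",
                  ("grip_strength",),
                  ("grip_strength", "sex", "bmi"),
                  q=0.2, direction="lowest", stratifiers=("sex", "bmi_group")),
        DomainDef("burden_cognition", "censored_sum",
                  ("flag__low_cognition", "proxy_cognition_poor"),
                  ("cognition_score", "proxy_cognition_poor")),
    ]
}


@dataclass(frozen=True)
class ModelSpec:
    """One frailty model: its domains/items, index range, cutoff and age rule."""

    model_id: str                      # FD | burden | BS
    domains: tuple[str, ...]           # domain names (FD/BS) or () for burden
    items: tuple[str, ...]             # scaled item columns (burden only)
    index_range: tuple[float, float]
    cutoff: float
    age_eligibility: int
    divisor: Optional[int] = None      # burden only; defaults to len(items)

    def __post_init__(self) -> None:
        lo, hi = self.index_range
        if not (lo <= self.cutoff <= hi):
            raise ValueError("cutoff must lie inside index_range")

    @property
    def index_column(self) -> str:
        return f"index__{self.model_id}"

    @property
    def status_column(self) -> str:
        return f"status__{self.model_id}"

    @property
    def eligibility_column(self) -> str:
        return f"eligible_{self.age_eligibility}"


#: the 24 equally weighted Burden items (scaled [0, 1] columns)
BURDEN_ITEMS = (
    ["domain__burden_cognition"]
    + [f"d{i:02d}" for i in range(1, 19)]
    + SCALED_ORDINALS
)

FD_MODEL = ModelSpec(
    model_id="FD",
    domains=("physical", "weight_loss", "cognitive", "sensory"),
    items=(),
    index_range=(0.0, 4.0),
    cutoff=2.0,
    age_eligibility=65,
)

BURDEN_MODEL = ModelSpec(
    model_id="burden",
    domains=(),
    items=tuple(BURDEN_ITEMS),
    index_range=(0.0, 1.0),
    cutoff=0.2,
    age_eligibility=70,
)

BS_MODEL = ModelSpec(
    model_id="BS",
    domains=("weight_loss", "exhaustion", "low_energy", "slowness", "weakness"),
    items=(),
    index_range=(0.0, 5.0),
    cutoff=3.0,
    age_eligibility=65,
)

DEFAULT_MODELS: dict[str, ModelSpec] = {
    "FD": FD_MODEL,
    "burden": BURDEN_MODEL,
    "BS": BS_MODEL,
}


def model_domains(model: ModelSpec) -> list[DomainDef]:
    """Domain recipes used by a model (the Burden cognition domain for burden)."""
    if model.model_id == "burden":
        return [DOMAIN_DEFS["burden_cognition"]]
    return [DOMAIN_DEFS[d] for d in model.domains]


def model_input_design_columns(model: ModelSpec) -> list[str]:
    """Numeric design columns representing a model's theory-based inputs.

    This is the union of the bias-regression designs of the model's domains,
    plus (for Burden) the scaled non-domain items; it is the column set
    against which bias is defined, so index = f(inputs) + biases exactly.
    """
    cols: list[str] = []
    for dom in model_domains(model):
        for c in dom.design:
            if c not in cols:
                cols.append(c)
    for item in model.items:
        if not item.startswith("domain__") and item not in cols:
            cols.append(item)
    return cols


def variable_catalogue() -> dict[str, VariableSpec]:
    """Spec for every raw input variable in the default menu."""
    cat: dict[str, VariableSpec] = {}
    for name in BINARY_INPUTS + BURDEN_DEFICITS:
        cat[name] = VariableSpec(name, "binary")
    for name in CONTINUOUS_INPUTS:
        cat[name] = VariableSpec(name, "continuous")
    for name, k in ORDINAL_INPUTS.items():
        cat[name] = VariableSpec(name, "ordinal", n_categories=k)
    return cat


# ---------------------------------------------------------------------------
# (De)serialization
# ---------------------------------------------------------------------------

def model_to_dict(model: ModelSpec) -> dict:
    return {
        "model_id": model.model_id,
        "domains": list(model.domains),
        "items": list(model.items),
        "index_range": list(model.index_range),
        "cutoff": model.cutoff,
        "age_eligibility": model.age_eligibility,
        "divisor": model.divisor,
    }


def model_from_dict(d: dict) -> ModelSpec:
    return ModelSpec(
        model_id=d["model_id"],
        domains=tuple(d.get("domains", ())),
        items=tuple(d.get("items", ())),
        index_range=tuple(d["index_range"]),
        cutoff=d["cutoff"],
        age_eligibility=d["age_eligibility"],
        divisor=d.get("divisor"),
    )


def save_model_spec(model: ModelSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)


def load_model_spec(path) -> ModelSpec:
    with open(path) as fh:
        return model_from_dict(yaml.safe_load(fh))
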