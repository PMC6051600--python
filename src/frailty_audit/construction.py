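"""Construction of the three frailty indices from deficit-level data.

The construction steps audited here are the classic ones: linear rescaling
of ordinal items to [0, 1], right-censored sums of binary indicators,
stratified extreme-quantile flags for continuous performance measures,
equal-weight summation, and dichotomization at a model-specific cutoff.

:class:`FrailtyIndexBuilder` is the estimator-shaped entry point: ``fit``
learns the stratum boundaries and quantile thresholds from a cohort,
``transform`` appends every derived column (scaled items, flags, domain
variables, indices and frailty statuses).  The module-level functions are
thin single-step wrappers used by the tests and the CLI.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .variables import (
    DOMAIN_DEFS,
    DEFAULT_MODELS,
    DomainDef,
    ModelSpec,
    ORDINAL_INPUTS,
)

WALK_CONVERSION = 15.0 / 8.0  # 8 ft walk time -> 15 ft walk time


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def rescale_ordinal(category_rank, n_categories: int):
    """Scale ordinal rank 1..K linearly onto [0, 1]: (rank - 1) / (K - 1).

    A 5-category item maps to {0, 0.25, 0.5, 0.75, 1}; a dichotomous item
    (K = 2) maps to {0, 1}.
    """
    if n_categories < 2:
        raise ValueError("n_categories must be >= 2")
    rank = np.asarray(category_rank, dtype=float)
    if np.any((rank < 1) | (rank > n_categories)):
        raise ValueError("category rank out of range 1..K")
    out = (rank - 1.0) / (n_categories - 1.0)
    return out.item() if np.isscalar(category_rank) else out


def censored_sum(indicator_values, cap: float = 1.0):
    """Sum binary indicators and right-censor the total at ``cap``.

    With two indicators and cap 1, a participant with both problems has a
    raw sum of 2 from which 1 is discarded — the censoring that the bias
    decomposition later recovers as manipulation-induced information.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    arr = np.asarray(indicator_values, dtype=float)
    if not np.all(np.isin(arr[~np.isnan(arr)], (0.0, 1.0))):
        raise ValueError("indicators must be binary (0/1)")
    total = np.nansum(arr, axis=0) if arr.ndim > 1 else float(np.nansum(arr))
    return np.minimum(total, cap)


def weighted_quantile_threshold(
    values: np.ndarray,
    q: float,
    direction: str = "lowest",
    weights: Optional[np.ndarray] = None,
) -> float:
    """Deterministic q-tail threshold.

    For ``lowest``: the smallest observed value v such that the (weighted)
    fraction of observations <= v reaches q.  For ``highest``: the mirror
    rule on the upper tail.  Ties at the threshold are all flagged, which is
    what lets the flagged fraction exceed q on tied or skew-weighted data.
    """
    if not (0.0 < q < 1.0):
        raise ValueError("q must lie in (0, 1)")
    values = np.asarray(values, dtype=float)
    keep = ~np.isnan(values)
    values = values[keep]
    if values.size == 0:
        raise ValueError("empty or all-missing stratum")
    if weights is None:
        weights = np.ones_like(values)
    else:
        weights = np.asarray(weights, dtype=float)[keep]
    sign = 1.0 if direction == "lowest" else -1.0
    if direction not in {"lowest", "highest"}:
        raise ValueError(f"unknown direction {direction!r}")
    order = np.argsort(sign * values, kind="stable")
    v = values[order]
    cum = np.cumsum(weights[order]) / np.sum(weights[order])
    pos = int(np.searchsorted(cum, q - 1e-12))
    pos = min(pos, len(v) - 1)
    return float(v[pos])


def stratified_quantile_flag(
    values,
    strata,
    q: float = 0.2,
    direction: str = "lowest",
    weights=None,
) -> np.ndarray:
    """Flag the extreme q-tail of a continuous measure within strata.

    ``strata`` is a Series/array of stratum labels (or a DataFrame whose
    rows are combined into labels).  Thresholds are computed per stratum
    from these same data; use :class:`FrailtyIndexBuilder` to learn on one
    sample and apply to another.
    """
    values = np.asarray(values, dtype=float)
    if isinstance(strata, pd.DataFrame):
        labels = pd.Series(
            list(map(tuple, strata.to_numpy())), index=range(len(values))
        )
    else:
        labels = pd.Series(np.asarray(strata), index=range(len(values)))
    if labels.isna().any():
        raise ValueError("every participant must be assigned a stratum")
    w = None if weights is None else np.asarray(weights, dtype=float)
    flags = np.zeros(len(values), dtype=int)
    for label, idx in labels.groupby(labels).groups.items():
        idx = np.asarray(idx)
        thr = weighted_quantile_threshold(
            values[idx], q, direction, None if w is None else w[idx]
        )
        if direction == "lowest":
            flags[idx] = (values[idx] <= thr).astype(int)
        else:
            flags[idx] = (values[idx] >= thr).astype(int)
    return flags


def weighted_prevalence(status, weights) -> float:
    """Survey-weighted prevalence: sum(w * status) / sum(w)."""
    status = np.asarray(status, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("all weights zero")
    return float(np.sum(weights * status) / total)


def dichotomize(index_values, model: ModelSpec) -> np.ndarray:
    """Frailty status: 1 iff index >= the model's cutoff (inclusive)."""
    idx = np.asarray(index_values, dtype=float)
    lo, hi = model.index_range
    if np.any((idx < lo - 1e-9) | (idx > hi + 1e-9)):
        raise ValueError(f"index outside declared range [{lo}, {hi}]")
    return (idx >= model.cutoff).astype(int)


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class FrailtyIndexBuilder(BaseEstimator, TransformerMixin):
    """Learn stratum boundaries / quantile thresholds and derive all frailty
    columns for the requested models.

    Parameters
    ----------
    models : sequence of model ids, default all three ("FD", "burden", "BS")
    weighted_quantiles : bool, default False
        Use survey-weighted quantiles for the flag thresholds.  The
        replication default is unweighted, matching the original Biologic
        Syndrome practice of computing percentiles on unweighted data.
    burden_divisor : int or None
        Divisor for the Burden scale; None uses the item count (24).
        Setting e.g. 30 reproduces the items-represented variant.
    """

    def __init__(
        self,
        models: Sequence[str] = ("FD", "burden", "BS"),
        weighted_quantiles: bool = False,
        burden_divisor: Optional[int] = None,
    ):
        self.models = models
        self.weighted_quantiles = weighted_quantiles
        self.burden_divisor = burden_divisor

    # -- threshold learning -------------------------------------------------

    def fit(self, X: pd.DataFrame, y=None) -> "FrailtyIndexBuilder":
        w = X["survey_weight"].to_numpy() if self.weighted_quantiles else None

        self.height_median_ = X.groupby("sex")["height"].median().to_dict()
        bmi = (X["weight_kg"] / X["height"] ** 2).rename("bmi")
        self.bmi_quartiles_ = {
            sex: grp.quantile([0.25, 0.5, 0.75]).to_numpy()
            for sex, grp in bmi.groupby(X["sex"])
        }

        base = X.copy()
        base["bmi"] = bmi
        base["walk_time_15ft"] = base["walk_time_8ft"] * WALK_CONVERSION
        base["height_group"] = self._height_group(base)
        base["bmi_group"] = self._bmi_group(base)

        def _thresholds(col, strata_cols, direction):
            out = {}
            if strata_cols:
                groups = base.groupby(list(strata_cols)).indices
            else:
                groups = {(): np.arange(len(base))}
            for label, idx in groups.items():
                key = label if isinstance(label, tuple) else (label,)
                idx = np.asarray(idx)
                out[key] = weighted_quantile_threshold(
                    base[col].to_numpy()[idx],
                    0.2,
                    direction,
                    None if w is None else w[idx],
                )
            return out

        self.thresholds_ = {
            "flag__low_cognition": _thresholds("cognition_score", (), "lowest"),
            "flag__low_activity": _thresholds("activity_score", ("sex",), "lowest"),
            "flag__slow_walk": _thresholds(
                "walk_time_15ft", ("sex", "height_group"), "highest"
            ),
            "flag__weak_grip": _thresholds(
                "grip_strength", ("sex", "bmi_group"), "lowest"
            ),
        }
        return self

    def _height_group(self, X: pd.DataFrame) -> np.ndarray:
        med = X["sex"].map(self.height_median_).to_numpy(dtype=float)
        return (X["height"].to_numpy() > med).astype(int)

    def _bmi_group(self, X: pd.DataFrame) -> np.ndarray:
        out = np.zeros(len(X), dtype=int)
        bmi = (X["weight_kg"] / X["height"] ** 2).to_numpy()
        for sex, cuts in self.bmi_quartiles_.items():
            m = (X["sex"] == sex).to_numpy()
            out[m] = np.searchsorted(cuts, bmi[m], side="right")
        return out

    def _apply_flag(self, X, col, source, strata_cols, direction) -> np.ndarray:
        thresholds = self.thresholds_[col]
        vals = X[source].to_numpy(dtype=float)
        flags = np.zeros(len(X), dtype=int)
        if strata_cols:
            groups = X.groupby(list(strata_cols)).indices
        else:
            groups = {(): np.arange(len(X))}
        for label, idx in groups.items():
            key = label if isinstance(label, tuple) else (label,)
            if key not in thresholds:
                raise ValueError(f"stratum {key!r} unseen at fit time for {col}")
            thr = thresholds[key]
            idx = np.asarray(idx)
            if direction == "lowest":
                flags[idx] = (vals[idx] <= thr).astype(int)
            else:
                flags[idx] = (vals[idx] >= thr).astype(int)
        return flags

    # -- derivation ---------------------------------------------------------

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        for name, k in ORDINAL_INPUTS.items():
            if name in out:
                out[f"scaled__{name}"] = rescale_ordinal(out[name].to_numpy(), k)
        out["walk_time_15ft"] = out["walk_time_8ft"] * WALK_CONVERSION
        out["bmi"] = out["weight_kg"] / out["height"] ** 2
        out["height_group"] = self._height_group(out)
        out["bmi_group"] = self._bmi_group(out)

        out["flag__low_cognition"] = self._apply_flag(
            out, "flag__low_cognition", "cognition_score", (), "lowest"
        )
        out["flag__low_activity"] = self._apply_flag(
            out, "flag__low_activity", "activity_score", ("sex",), "lowest"
        )
        out["flag__slow_walk"] = self._apply_flag(
            out, "flag__slow_walk", "walk_time_15ft", ("sex", "height_group"), "highest"
        )
        out["flag__weak_grip"] = self._apply_flag(
            out, "flag__weak_grip", "grip_strength", ("sex", "bmi_group"), "lowest"
        )

        for dom in DOMAIN_DEFS.values():
            self._build_domain(out, dom)

        for mid in self.models:
            model = self._model(mid)
            out[model.index_column] = build_index(out, model)
            out[model.status_column] = dichotomize(
                out[model.index_column].to_numpy(), model
            )
        return out

    def _model(self, mid: str) -> ModelSpec:
        model = DEFAULT_MODELS[mid]
        if mid == "burden" and self.burden_divisor is not None:
            from dataclasses import replace

            model = replace(model, divisor=self.burden_divisor)
        return model

    @staticmethod
    def _build_domain(out: pd.DataFrame, dom: DomainDef) -> None:
        if dom.method == "censored_sum":
            missing = [c for c in dom.inputs if c not in out.columns]
            if missing:
                raise KeyError(f"domain {dom.name!r} missing inputs {missing}")
            raw = out[list(dom.inputs)].to_numpy(dtype=float).sum(axis=1)
            out[f"sum__{dom.name}"] = raw
            out[dom.column] = np.minimum(raw, 1.0)
        else:  # quantile_flag domains reuse the already-derived flags
            flag_col = {
                "low_energy": "flag__low_activity",
                "slowness": "flag__slow_walk",
                "weakness": "flag__weak_grip",
            }[dom.name]
            out[dom.column] = out[flag_col].astype(float)


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def build_domain(table: pd.DataFrame, domain: str | DomainDef) -> pd.Series:
    """Compute one domain variable on a table that already holds the needed
    raw and derived columns (fit-and-apply on the same data)."""
    dom = DOMAIN_DEFS[domain] if isinstance(domain, str) else domain
    tmp = table.copy()
    if dom.method == "quantile_flag":
        builder = FrailtyIndexBuilder(models=()).fit(table)
        tmp = builder.transform(table)
    else:
        FrailtyIndexBuilder._build_domain(tmp, dom)
    return tmp[dom.column]


def build_index(table: pd.DataFrame, model: ModelSpec) -> pd.Series:
    """Sum a model's domain variables (FD, BS) or scaled items over the
    divisor (Burden)."""
    if model.model_id == "burden":
        cols = list(model.items)
        missing = [c for c in cols if c not in table.columns]
        if missing:
            raise KeyError(f"burden items missing: {missing}")
        divisor = model.divisor if model.divisor is not None else len(cols)
        values = table[cols].to_numpy(dtype=float).sum(axis=1) / divisor
    else:
        cols = [f"domain__{d}" for d in model.domains]
        missing = [c for c in cols if c not in table.columns]
        if missing:
            raise KeyError(f"domain columns missing: {missing}")
        if len(cols) != len(model.domains):
            raise ValueError("domain count mismatch with ModelSpec")
        values = table[cols].to_numpy(dtype=float).sum(axis=1)
    return pd.Series(values, index=table.index, name=model.index_column)
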