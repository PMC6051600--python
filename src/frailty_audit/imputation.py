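"""Missing-value handling: chained-equations imputation, or the
missing-as-category shortcut used for temporary index construction.

The chained-equations imputer cycles through the incomplete variables,
regressing each on all other analysis variables (linear models for
continuous measures, logistic / multinomial models for binary and ordinal
items) and replacing missing cells with stochastic draws from the fitted
conditional distribution.  One completed dataset is returned, deterministic
given the seed.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LinearRegression, LogisticRegression

from .variables import RAW_INPUTS, variable_catalogue


def _predictor_frame(table: pd.DataFrame, exclude: str, analysis_cols: list[str]) -> pd.DataFrame:
    cols = {}
    cols["age"] = table["age"].astype(float)
    cols["sex_female"] = (table["sex"] == "female").astype(float)
    for c in analysis_cols:
        if c != exclude:
            cols[c] = table[c].astype(float)
    return pd.DataFrame(cols, index=table.index)


class ChainedImputer(BaseEstimator, TransformerMixin):
    """MICE-style single imputation over the raw input variables.

    Parameters
    ----------
    n_iterations : cycles through the incomplete variables (default 10)
    random_state : seed for initialization and posterior draws
    """

    def __init__(self, n_iterations: int = 10, random_state: int = 0):
        self.n_iterations = n_iterations
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None) -> "ChainedImputer":
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return impute_chained(X, self.n_iterations, self.random_state)

    def fit_transform(self, X: pd.DataFrame, y=None, **kw) -> pd.DataFrame:
        return self.transform(X)


def impute_chained(
    table: pd.DataFrame,
    n_iterations: int = 10,
    seed: int = 0,
    columns: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Return a single completed copy of ``table``.

    Tables without missing cells are returned unchanged (a copy).
    """
    cat = variable_catalogue()
    if columns is None:
        columns = [c for c in RAW_INPUTS if c in table.columns]
    incomplete = [c for c in columns if table[c].isna().any()]
    out = table.copy()
    if not incomplete:
        return out
    rng = np.random.default_rng(seed)

    masks = {c: table[c].isna().to_numpy() for c in incomplete}
    for c in incomplete:
        observed = table[c].dropna().to_numpy()
        if observed.size == 0:
            raise ValueError(f"column {c!r} has no observed values")
        out.loc[masks[c], c] = rng.choice(observed, size=masks[c].sum())

    analysis_cols = [c for c in columns]
    for _ in range(n_iterations):
        for c in sorted(incomplete):
            mask = masks[c]
            kind = cat[c].kind if c in cat else "continuous"
            Xall = _predictor_frame(out, c, analysis_cols)
            X_obs, X_mis = Xall[~mask], Xall[mask]
            y_obs = table.loc[~mask, c].to_numpy(dtype=float)

            if kind == "continuous":
                reg = LinearRegression().fit(X_obs, y_obs)
                pred = reg.predict(X_mis)
                resid_sd = float(np.std(y_obs - reg.predict(X_obs)))
                draws = pred + rng.normal(0.0, resid_sd, size=len(pred))
                lo, hi = np.min(y_obs), np.max(y_obs)
                out.loc[mask, c] = np.clip(draws, lo, hi)
            else:
                classes = np.unique(y_obs)
                if len(classes) == 1:
                    out.loc[mask, c] = classes[0]
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    clf = LogisticRegression(max_iter=500).fit(
                        X_obs, y_obs.astype(int)
                    )
                proba = clf.predict_proba(X_mis)
                cum = np.cumsum(proba, axis=1)
                u = rng.random(len(X_mis))[:, None]
                pick = (u > cum).sum(axis=1)
                out.loc[mask, c] = clf.classes_[pick]
    for c in incomplete:
        if c in cat and cat[c].kind in ("binary", "ordinal"):
            out[c] = out[c].astype(float).round().astype(int)
    return out


def fill_missing_as_zero(
    table: pd.DataFrame, columns: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Missing-as-category handling for temporary indices: a missing item
    contributes no deficit (binary/ordinal -> lowest category, continuous
    -> column median so it never lands in an extreme quantile tail)."""
    cat = variable_catalogue()
    if columns is None:
        columns = [c for c in RAW_INPUTS if c in table.columns]
    out = table.copy()
    for c in columns:
        if not out[c].isna().any():
            continue
        kind = cat[c].kind if c in cat else "continuous"
        if kind == "binary":
            out[c] = out[c].fillna(0).astype(int)
        elif kind == "ordinal":
            out[c] = out[c].fillna(1).astype(int)
        else:
            out[c] = out[c].fillna(out[c].median())
    return out
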