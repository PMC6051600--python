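"""Decomposition of frailty indices into input-variable information plus
manipulation-induced bias.

A *bias variable* is the least-squares residual of a derived domain
variable on the theory-based input columns that were used to create it:
the part of the domain that censoring, categorization or quantile
thresholding introduced and that no linear function of the inputs can
reproduce.  By construction each constructed index is an exact linear
combination of its input columns and its bias variables, so regressing the
index on inputs + biases returns R-squared of 1; regressing on inputs only
quantifies how much of the index is input information.

Dichotomization bias — status minus continuous index — is reported
separately: it is the information added by thresholding the index itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .variables import (
    DOMAIN_DEFS,
    DEFAULT_MODELS,
    ModelSpec,
    model_domains,
    model_input_design_columns,
)


def _design_matrix(table: pd.DataFrame, columns: Sequence[str]) -> np.ndarray:
    """Numeric design for the given columns; sex is encoded as a female
    indicator, everything else must already be numeric."""
    cols = []
    for c in columns:
        if c == "sex":
            cols.append((table["sex"] == "female").astype(float).to_numpy())
        else:
            cols.append(table[c].to_numpy(dtype=float))
    return np.column_stack(cols) if cols else np.empty((len(table), 0))


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares fit with intercept via pseudo-inverse (rank-deficient
    designs are resolved to the minimum-norm solution, never an error).

    Returns (fitted, residuals, r_squared)."""
    Xc = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
    fitted = Xc @ beta
    resid = y - fitted
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return fitted, resid, r2


@dataclass
class BiasResult:
    """Residual bias of one domain with its fit diagnostics."""

    source: str
    bias: np.ndarray
    fitted: np.ndarray
    r_squared: float


def domain_bias(domain_values, input_design) -> BiasResult:
    """OLS residual of a domain variable on its own input design columns.

    ``input_design`` is an array/DataFrame of numeric columns.  The residual
    has mean ~0 and is orthogonal to the inputs by construction.
    """
    y = np.asarray(domain_values, dtype=float)
    X = np.asarray(input_design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] < 1:
        raise ValueError("at least one input column is required")
    fitted, resid, r2 = _ols(y, X)
    return BiasResult("domain", resid, fitted, r2)


def dichotomization_bias(index_values, cutoff: float) -> np.ndarray:
    """Status minus index: the additive term that turns the continuous
    index into the 0/1 status (status = index + bias).

    An index of 0.9 at cutoff 0.2 needs +0.1; an index of 0.1 needs -0.1.
    """
    idx = np.asarray(index_values, dtype=float)
    status = (idx >= cutoff).astype(float)
    return status - idx


class BiasDecomposer(BaseEstimator, TransformerMixin):
    """Compute the nine domain-level bias variables on a constructed cohort.

    ``fit`` stores the per-domain OLS coefficients; ``transform`` appends a
    ``bias__<domain>`` column per domain present in the table.
    """

    def __init__(self, domains: Optional[Sequence[str]] = None):
        self.domains = domains

    def fit(self, X: pd.DataFrame, y=None) -> "BiasDecomposer":
        names = list(self.domains) if self.domains else list(DOMAIN_DEFS)
        self.coef_: dict[str, np.ndarray] = {}
        self.design_cols_: dict[str, tuple[str, ...]] = {}
        self.r_squared_: dict[str, float] = {}
        for name in names:
            dom = DOMAIN_DEFS[name]
            if dom.column not in X.columns:
                continue
            D = _design_matrix(X, dom.design)
            yv = X[dom.column].to_numpy(dtype=float)
            Xc = np.column_stack([np.ones(len(yv)), D])
            beta, *_ = np.linalg.lstsq(Xc, yv, rcond=None)
            self.coef_[name] = beta
            self.design_cols_[name] = dom.design
            fitted = Xc @ beta
            ss_tot = float(np.sum((yv - yv.mean()) ** 2))
            self.r_squared_[name] = (
                1.0 if ss_tot == 0
                else 1.0 - float(np.sum((yv - fitted) ** 2)) / ss_tot
            )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        for name, beta in self.coef_.items():
            dom = DOMAIN_DEFS[name]
            D = _design_matrix(out, self.design_cols_[name])
            fitted = np.column_stack([np.ones(len(out)), D]) @ beta
            out[f"bias__{name}"] = out[dom.column].to_numpy(dtype=float) - fitted
        return out


def model_bias_columns(model: ModelSpec) -> list[str]:
    """Names of the bias columns belonging to one model."""
    return [f"bias__{d.name}" for d in model_domains(model)]


def index_bias_share(
    table: pd.DataFrame,
    model: ModelSpec | str,
    input_columns: Optional[Sequence[str]] = None,
    bias_columns: Optional[Sequence[str]] = None,
) -> dict[str, float]:
    """R-squared of a constructed index on (a) its input columns, (b) its
    bias columns, (c) both.  ``r2_both`` is 1 by construction; ``1 -
    r2_inputs`` is the share of index variance introduced purely by data
    manipulation."""
    if isinstance(model, str):
        model = DEFAULT_MODELS[model]
    y = table[model.index_column].to_numpy(dtype=float)
    if np.var(y) == 0:
        raise ValueError("index has zero variance")
    inputs = list(input_columns or model_input_design_columns(model))
    biases = list(bias_columns or model_bias_columns(model))
    Xi = _design_matrix(table, inputs)
    Xb = _design_matrix(table, biases)
    _, _, r2_inputs = _ols(y, Xi)
    _, _, r2_bias = _ols(y, Xb)
    _, _, r2_both = _ols(y, np.column_stack([Xi, Xb]))
    return {
        "r2_inputs": r2_inputs,
        "r2_bias": r2_bias,
        "r2_both": r2_both,
        "unexplained_by_inputs": 1.0 - r2_inputs,
    }
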