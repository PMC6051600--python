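"""Discrete-time survival analysis of mortality.

One-row-per-participant follow-up is expanded to a person-period table
(one row per participant per year at risk); yearly death is modelled with
logistic regression on a saturated set of period dummies (one baseline
log-odds per year) plus predictors and adjustment covariates.  With period
dummies only, the fitted hazards reproduce the Kaplan-Meier estimate
exactly, which anchors the implementation.

:func:`compare_representations` is the head-to-head machinery: the same
covariate-adjusted hazard model is fitted once per representation of a
frailty model (continuous index, dichotomous status, domain variables,
bias variables, raw inputs, and the equal-weight sum of the inputs) and
scored by AUC (with DeLong CI), AIC and residual deviance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from sklearn.base import BaseEstimator

from .bias import model_bias_columns
from .interpretation import auc_with_ci
from .variables import DEFAULT_MODELS, ModelSpec, model_input_design_columns

DEFAULT_COVARIATES = ("sex", "race_ethnicity", "education", "income_pc", "wealth_pc")


def to_person_period(
    cohort: pd.DataFrame, columns: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Expand to one row per participant-year.

    A participant followed for f years contributes f rows with periods
    1..f; ``event`` is 1 only on the last row of those who died.
    """
    f = cohort["followup_time"].to_numpy(dtype=float)
    if np.any(~np.isfinite(f)) or np.any(f < 1):
        raise ValueError("followup_time must be >= 1 for every participant")
    f = f.astype(int)
    died = cohort["died"].to_numpy(dtype=int)
    idx = np.repeat(np.arange(len(cohort)), f)
    period = np.concatenate([np.arange(1, fi + 1) for fi in f])
    event = np.zeros(len(period), dtype=int)
    last = np.cumsum(f) - 1
    event[last] = died
    keep = list(columns) if columns is not None else list(cohort.columns)
    pp = cohort.iloc[idx][keep].reset_index(drop=True)
    pp["period"] = period
    pp["event"] = event
    return pp


def km_curve(cohort: pd.DataFrame, by: Optional[str] = None) -> pd.DataFrame:
    """Kaplan-Meier survival function at yearly steps (product-limit)."""
    times = np.arange(0, int(cohort["followup_time"].max()) + 1)

    def _one(sub: pd.DataFrame) -> pd.DataFrame:
        km = KaplanMeierFitter()
        km.fit(sub["followup_time"], event_observed=sub["died"], timeline=times)
        out = km.survival_function_.reset_index()
        out.columns = ["year", "survival"]
        return out

    if by is None:
        return _one(cohort)
    parts = []
    for level, sub in cohort.groupby(by):
        part = _one(sub)
        part[by] = level
        parts.append(part)
    return pd.concat(parts, ignore_index=True)


def covariate_design(df: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Numeric design for adjustment covariates: sex as a female indicator,
    race/ethnicity as dummy columns (first level dropped), others as is."""
    cols = {}
    for c in covariates:
        if c == "sex":
            cols["sex_female"] = (df["sex"] == "female").astype(float)
        elif c == "race_ethnicity":
            dummies = pd.get_dummies(df["race_ethnicity"], prefix="race", dtype=float)
            for dc in sorted(dummies.columns)[1:]:
                cols[dc] = dummies[dc]
        else:
            cols[c] = df[c].astype(float)
    return pd.DataFrame(cols, index=df.index)


@dataclass
class HazardFit:
    """Fitted discrete-time hazard model."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    llf: float
    aic: float
    deviance: float
    null_deviance: float
    predicted: np.ndarray
    events: np.ndarray
    converged: bool
    predictor_terms: tuple[str, ...]
    n_rows: int
    n_dropped: int = 0

    def predictor_pvalues(self) -> pd.Series:
        return self.pvalues[list(self.predictor_terms)]


class DiscreteTimeHazard(BaseEstimator):
    """Person-period logistic hazard model (scikit-learn estimator shape).

    ``fit`` takes a person-period table; the design is saturated period
    dummies (no separate intercept) + predictors + covariates.  Rows with
    missing covariate or predictor values are dropped with a logged count.
    """

    def __init__(
        self,
        predictors: Sequence[str] = (),
        covariates: Sequence[str] = (),
    ):
        self.predictors = predictors
        self.covariates = covariates

    def fit(self, pp: pd.DataFrame, y=None) -> "DiscreteTimeHazard":
        predictors = list(self.predictors)
        design_parts = [
            pd.get_dummies(pp["period"].astype(int), prefix="period", dtype=float)
        ]
        if predictors:
            pred = pp[predictors].astype(float)
            pred.columns = predictors
            design_parts.append(pred)
        if self.covariates:
            design_parts.append(covariate_design(pp, self.covariates))
        X = pd.concat(design_parts, axis=1)
        yv = pp["event"].astype(float)

        keep = ~X.isna().any(axis=1) & yv.notna()
        n_dropped = int((~keep).sum())
        X, yv = X[keep], yv[keep]

        const_pred = [c for c in predictors if X[c].nunique() <= 1]
        if const_pred:
            raise ValueError(f"constant predictors: {const_pred}")

        converged = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(yv, X, family=sm.families.Binomial())
            try:
                res = model.fit(maxiter=200)
                converged = bool(getattr(res, "converged", True))
            except Exception:
                res = model.fit_regularized(alpha=1e-8, maxiter=200)
                converged = False

        self.result_ = res
        self.fit_ = HazardFit(
            params=res.params,
            bse=res.bse,
            pvalues=res.pvalues,
            llf=float(res.llf),
            aic=float(res.aic),
            deviance=float(res.deviance),
            null_deviance=float(res.null_deviance),
            predicted=np.asarray(res.predict(X)),
            events=yv.to_numpy(),
            converged=converged,
            predictor_terms=tuple(predictors),
            n_rows=int(len(yv)),
            n_dropped=n_dropped,
        )
        self.events_ = yv.to_numpy()
        return self


def fit_discrete_time(
    pp: pd.DataFrame,
    predictors: Sequence[str] = (),
    covariates: Sequence[str] = (),
) -> HazardFit:
    """Fit the discrete-time hazard model and return the :class:`HazardFit`."""
    est = DiscreteTimeHazard(predictors=predictors, covariates=covariates)
    est.fit(pp)
    return est.fit_


def representation_columns(model: ModelSpec, table: pd.DataFrame) -> dict[str, list[str]]:
    """Predictor column sets for the head-to-head comparison."""
    if model.model_id == "burden":
        domains = ["domain__burden_cognition"]
    else:
        domains = [f"domain__{d}" for d in model.domains]
    inputs = [c for c in model_input_design_columns(model) if c != "sex"]
    reps = {
        "index": [model.index_column],
        "status": [model.status_column],
        "domains": domains,
        "bias": [c for c in model_bias_columns(model) if c in table.columns],
        "inputs": inputs,
        "inputs_sum": ["__equal_weight_inputs__"],
    }
    return reps


def compare_representations(
    table: pd.DataFrame,
    model: ModelSpec | str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    restrict_eligible: bool = True,
) -> pd.DataFrame:
    """Fit one covariate-adjusted hazard model per index representation and
    report AUC (DeLong 95% CI), AIC, residual deviance and the number of
    representation terms with Wald p < 0.05."""
    if isinstance(model, str):
        model = DEFAULT_MODELS[model]
    sub = table
    if restrict_eligible and model.eligibility_column in table.columns:
        sub = table[table[model.eligibility_column] == 1]
    sub = sub.copy()
    inputs = [c for c in model_input_design_columns(model) if c != "sex"]
    sub["__equal_weight_inputs__"] = sub[inputs].astype(float).sum(axis=1)

    pp = to_person_period(sub)
    rows = []
    for rep, cols in representation_columns(model, sub).items():
        fit = fit_discrete_time(pp, predictors=cols, covariates=covariates)
        auc = auc_with_ci(fit.predicted, fit.events)
        n_sig = int((fit.predictor_pvalues() < 0.05).sum())
        rows.append(
            {
                "model": model.model_id,
                "representation": rep,
                "n_predictors": len(cols),
                "n_significant": n_sig,
                "auc": auc["auc"],
                "auc_ci_low": auc["ci_low"],
                "auc_ci_high": auc["ci_high"],
                "aic": fit.aic,
                "residual_deviance": fit.deviance,
                "null_deviance": fit.null_deviance,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)
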