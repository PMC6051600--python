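"""Interpretation of indices and statuses by forward-stepwise approximation.

A continuous index is approximated with forward-stepwise *linear*
regression, a dichotomous status with forward-stepwise *logistic*
regression; both add at each step the candidate that minimizes AIC and stop
when no candidate lowers it.  The recorded path yields the R-squared curve
(how fast the index is explained as variables accrue), the number of
variables needed to reach a stated fraction of the attainable R-squared
(the simplification question), and — for statuses — ROC AUC with a DeLong
95% confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator


@dataclass
class SelectionPath:
    """Ordered record of a forward-stepwise run."""

    family: str
    null_aic: float
    steps: pd.DataFrame            # step, variable, aic, fit statistics
    selected: list[str] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.steps)


def _fit(y: np.ndarray, X: np.ndarray, family: str):
    if family == "linear":
        return sm.OLS(y, X).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.Logit(y, X).fit(disp=0, maxiter=200)


def _stats_for(res, family: str, k: int, llnull: float, y, X) -> dict:
    if family == "linear":
        return {"r2": res.rsquared, "adj_r2": res.rsquared_adj}
    mcf = 1.0 - res.llf / llnull if llnull != 0 else 0.0
    adj = 1.0 - (res.llf - k) / llnull if llnull != 0 else 0.0
    auc = auc_with_ci(res.predict(X), y)["auc"] if len(np.unique(y)) == 2 else np.nan
    return {"pseudo_r2": mcf, "adj_pseudo_r2": adj, "auc": auc}


class ForwardStepwiseSelector(BaseEstimator):
    """Forward-stepwise AIC selection (scikit-learn estimator shape).

    Parameters
    ----------
    family : "linear" or "logistic"
    max_steps : int or None (candidate count)
    candidate_groups : mapping name -> list of columns
        Categorical candidates enter as whole dummy blocks; default is one
        candidate per column.
    """

    def __init__(
        self,
        family: str = "linear",
        max_steps: Optional[int] = None,
        candidate_groups: Optional[Mapping[str, Sequence[str]]] = None,
    ):
        self.family = family
        self.max_steps = max_steps
        self.candidate_groups = candidate_groups

    def fit(self, X: pd.DataFrame, y) -> "ForwardStepwiseSelector":
        if self.family not in {"linear", "logistic"}:
            raise ValueError("family must be 'linear' or 'logistic'")
        y = np.asarray(y, dtype=float)
        if np.var(y) == 0:
            raise ValueError("response is constant")
        groups = (
            {name: list(cols) for name, cols in self.candidate_groups.items()}
            if self.candidate_groups
            else {c: [c] for c in X.columns}
        )
        # deterministic tie-break: candidates examined in name order
        remaining = sorted(groups)
        max_steps = self.max_steps or len(remaining)

        n = len(y)
        ones = np.ones((n, 1))
        null_res = _fit(y, ones, self.family)
        llnull = null_res.llf
        current_aic = null_res.aic
        current_cols: list[str] = []
        rows, selected, skipped = [], [], []

        for step in range(1, max_steps + 1):
            best = None
            for name in remaining:
                cols = current_cols + groups[name]
                design = np.column_stack([ones, X[cols].to_numpy(dtype=float)])
                try:
                    res = _fit(y, design, self.family)
                    aic = res.aic
                    if not np.isfinite(aic):
                        raise ValueError("non-finite AIC")
                except Exception:
                    if name not in skipped:
                        skipped.append(name)
                    continue
                if best is None or aic < best[0] - 1e-12:
                    best = (aic, name, res, design)
            if best is None or best[0] >= current_aic:
                break
            aic, name, res, design = best
            current_cols += groups[name]
            current_aic = aic
            remaining.remove(name)
            selected.append(name)
            row = {"step": step, "variable": name, "aic": aic}
            row.update(
                _stats_for(res, self.family, design.shape[1], llnull, y, design)
            )
            rows.append(row)

        stat_cols = (
            ["r2", "adj_r2"]
            if self.family == "linear"
            else ["pseudo_r2", "adj_pseudo_r2", "auc"]
        )
        self.path_ = SelectionPath(
            family=self.family,
            null_aic=null_res.aic,
            steps=pd.DataFrame(rows, columns=["step", "variable", "aic"] + stat_cols),
            selected=selected,
            skipped=skipped,
        )
        self.selected_ = selected
        return self


def forward_stepwise(
    response,
    candidates: pd.DataFrame,
    family: str = "linear",
    max_steps: Optional[int] = None,
    candidate_groups: Optional[Mapping[str, Sequence[str]]] = None,
) -> SelectionPath:
    """Functional wrapper over :class:`ForwardStepwiseSelector`."""
    sel = ForwardStepwiseSelector(
        family=family, max_steps=max_steps, candidate_groups=candidate_groups
    )
    sel.fit(candidates, response)
    return sel.path_


def r2_curve(path: SelectionPath) -> pd.DataFrame:
    """(step, fit statistic) table for plotting the approximation curve."""
    if len(path) == 0:
        raise ValueError("empty selection path")
    stat = "r2" if path.family == "linear" else "pseudo_r2"
    return path.steps[["step", "variable", stat]].rename(columns={stat: "statistic"})


def variables_to_reach(path: SelectionPath, fraction: float) -> Optional[int]:
    """Smallest number of selected variables whose cumulative R-squared
    reaches ``fraction`` of the maximum attained along the path; None if
    unreached."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    curve = r2_curve(path)["statistic"].to_numpy()
    target = fraction * np.max(curve)
    hits = np.nonzero(curve >= target - 1e-12)[0]
    return int(hits[0]) + 1 if hits.size else None


# ---------------------------------------------------------------------------
# AUC with DeLong confidence interval
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def auc_with_ci(scores, labels, level: float = 0.95) -> dict[str, float]:
    """Rank-based AUC (ties count one half) with a DeLong-type confidence
    interval, clipped to [0, 1]."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    # structural components (DeLong): V10 over positives, V01 over negatives
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(np.mean(v10))
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    half = zcrit * np.sqrt(max(var, 0.0))
    return {
        "auc": auc,
        "ci_low": float(np.clip(auc - half, 0.0, 1.0)),
        "ci_high": float(np.clip(auc + half, 0.0, 1.0)),
    }
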