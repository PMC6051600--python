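"""End-to-end orchestration of the frailty-index audit.

The nine-step workflow: simulate (or load) a cohort; handle missing values;
construct the three frailty indices; compute the bias decomposition;
interpret each index by forward-stepwise approximation; compare index
representations in the discrete-time hazard model; mine equal-weight
alternative indices; and assemble a report with per-model prevalence,
variance-share, simplification, survival-comparison and mining summaries.
Every stage writes its intermediate table so each reported number can be
recomputed from a stored file, and the whole run is deterministic given the
configured seeds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .bias import BiasDecomposer, index_bias_share, model_bias_columns
from .cohort import CohortSpec, read_cohort, simulate, write_cohort
from .construction import FrailtyIndexBuilder, weighted_prevalence
from .imputation import fill_missing_as_zero, impute_chained
from .interpretation import forward_stepwise, variables_to_reach
from .mining import mine, summarize
from .survival import (
    DEFAULT_COVARIATES,
    compare_representations,
    fit_discrete_time,
    to_person_period,
)
from .variables import (
    DEFAULT_MODELS,
    model_input_design_columns,
)

#: desk-scale default mining pool (12 variables -> 495 candidate indices)
DEFAULT_MINING_POOL = [f"d{i:02d}" for i in range(1, 13)]


@dataclass
class RunConfig:
    """Configuration for one full audit run."""

    cohort_spec: Optional[CohortSpec] = None
    cohort_path: Optional[str] = None
    missing_mode: str = "chained-imputation"   # or "as-category"
    models: Sequence[str] = ("FD", "burden", "BS")
    mining_pool: Sequence[str] = tuple(DEFAULT_MINING_POOL)
    mining_k: int = 4
    interpret_max_steps: Optional[int] = None
    imputation_iterations: int = 5
    seed: int = 0
    outdir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.missing_mode not in {"chained-imputation", "as-category"}:
            raise ValueError(f"unknown missing mode {self.missing_mode!r}")
        if self.cohort_spec is None and self.cohort_path is None:
            self.cohort_spec = CohortSpec(seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        spec = raw.pop("cohort_spec", None)
        cfg = cls(**raw)
        if spec is not None:
            if "age_range" in spec:
                spec["age_range"] = tuple(spec["age_range"])
            cfg.cohort_spec = CohortSpec(**spec)
        return cfg


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    return obj


def run_full(config: RunConfig) -> dict:
    """Execute the whole audit and return the report bundle (a dict)."""
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report").mkdir(exist_ok=True)
    log: list[str] = []

    # 1-2. cohort + missing handling -------------------------------------
    if config.cohort_path:
        cohort = read_cohort(config.cohort_path)
        log.append(f"loaded cohort from {config.cohort_path} (n={len(cohort)})")
    else:
        cohort = simulate(config.cohort_spec)
        log.append(f"simulated cohort (n={len(cohort)}, seed={config.cohort_spec.seed})")
    n_missing_cells = int(cohort.isna().sum().sum())
    if n_missing_cells:
        if config.missing_mode == "chained-imputation":
            cohort = impute_chained(
                cohort, config.imputation_iterations, seed=config.seed + 101
            )
            log.append(f"imputed {n_missing_cells} missing cells by chained equations")
        else:
            cohort = fill_missing_as_zero(cohort)
            log.append(f"filled {n_missing_cells} missing cells as no-deficit categories")

    # 3-4. construction + bias -------------------------------------------
    builder = FrailtyIndexBuilder(models=tuple(config.models)).fit(cohort)
    table = builder.transform(cohort)
    table = BiasDecomposer().fit(table).transform(table)
    if outdir:
        write_cohort(table, outdir / "indexed.csv")

    report: dict = {"config_seed": config.seed, "n_participants": len(table), "models": {}}

    for mid in config.models:
        model = DEFAULT_MODELS[mid]
        elig = table[model.eligibility_column] == 1
        w = table["survey_weight"]
        status = table[model.status_column]
        entry: dict = {
            "weighted_prevalence_overall": weighted_prevalence(status, w),
            "weighted_prevalence_eligible": weighted_prevalence(status[elig], w[elig]),
            "weighted_prevalence_younger": weighted_prevalence(status[~elig], w[~elig]),
            "unweighted_prevalence_eligible": float(status[elig].mean()),
            "unweighted_prevalence_younger": float(status[~elig].mean()),
        }

        # 5. variance shares ---------------------------------------------
        entry["variance_shares"] = index_bias_share(table, model)

        # 6. interpretation ----------------------------------------------
        inputs = model_input_design_columns(model)
        design = table.copy()
        design["sex"] = (design["sex"] == "female").astype(float)
        path_inputs = forward_stepwise(
            table[model.index_column],
            design[inputs],
            family="linear",
            max_steps=config.interpret_max_steps,
        )
        both_cols = inputs + [
            c for c in model_bias_columns(model) if c in table.columns
        ]
        path_both = forward_stepwise(
            table[model.index_column],
            design[both_cols],
            family="linear",
            max_steps=config.interpret_max_steps,
        )
        entry["interpretation"] = {
            "max_r2_inputs": float(path_inputs.steps["r2"].max()),
            "n_variables_max_r2_inputs": int(len(path_inputs)),
            "max_r2_both": float(path_both.steps["r2"].max()),
            "variables_to_reach_90": variables_to_reach(path_inputs, 0.90),
            "variables_to_reach_95": variables_to_reach(path_inputs, 0.95),
            "variables_to_reach_99": variables_to_reach(path_inputs, 0.99),
            "selection_order_inputs": path_inputs.selected,
        }
        if outdir:
            path_inputs.steps.to_csv(
                outdir / f"selection_path_{mid}_inputs.csv", index=False
            )
            path_both.steps.to_csv(
                outdir / f"selection_path_{mid}_both.csv", index=False
            )

        # 7. survival comparison -----------------------------------------
        comparison = compare_representations(table, model)
        entry["survival_comparison"] = comparison.drop(columns=["model"])
        if outdir:
            comparison.to_csv(outdir / f"survival_comparison_{mid}.csv", index=False)

        report["models"][mid] = entry

    # 8. mining ----------------------------------------------------------
    mining_model = config.models[0] if config.models else "FD"
    model = DEFAULT_MODELS[mining_model]
    elig_table = table[table[model.eligibility_column] == 1]
    pp = to_person_period(elig_table)
    ref_fit = fit_discrete_time(
        pp, predictors=[model.index_column], covariates=DEFAULT_COVARIATES
    )
    results = mine(
        table,
        pool=list(config.mining_pool),
        k=config.mining_k,
        model=model,
        checkpoint_path=(outdir / "mining.csv") if outdir else None,
    )
    report["mining"] = {
        "reference_model": mining_model,
        **summarize(results, reference_fit=ref_fit),
        "n_skipped_unmeasured": results.attrs["n_skipped_unmeasured"],
    }

    report["log"] = log
    report = _jsonable(report)
    if outdir:
        table1 = {
            mid: {
                k: v
                for k, v in report["models"][mid].items()
                if k != "survival_comparison"
            }
            for mid in report["models"]
        }
        table2 = {
            mid: report["models"][mid]["survival_comparison"]
            for mid in report["models"]
        }
        table2["mining"] = report["mining"]
        with open(outdir / "report" / "table1.json", "w") as fh:
            json.dump(table1, fh, indent=1, sort_keys=True)
        with open(outdir / "report" / "table2.json", "w") as fh:
            json.dump(table2, fh, indent=1, sort_keys=True)
        with open(outdir / "run.log", "w") as fh:
            fh.write("\n".join(log) + "\n")
    return report


def render_markdown(report: dict) -> str:
    """Human-readable prevalence / variance-share / survival summary."""
    lines = ["# Frailty index audit", ""]
    for mid, entry in report.get("models", {}).items():
        lines.append(f"## Model {mid}")
        lines.append(
            f"- weighted prevalence (eligible): "
            f"{entry['weighted_prevalence_eligible']:.3f}"
        )
        lines.append(
            f"- weighted prevalence (younger): "
            f"{entry['weighted_prevalence_younger']:.3f}"
        )
        vs = entry["variance_shares"]
        lines.append(
            f"- R2 inputs {vs['r2_inputs']:.4f}; R2 bias {vs['r2_bias']:.4f}; "
            f"R2 both {vs['r2_both']:.6f}"
        )
        interp = entry["interpretation"]
        lines.append(
            f"- variables to reach 90%/95%/99% of max R2: "
            f"{interp['variables_to_reach_90']}/{interp['variables_to_reach_95']}"
            f"/{interp['variables_to_reach_99']}"
        )
        lines.append("")
    if "mining" in report:
        m = report["mining"]
        lines.append("## Alternative-index mining")
        lines.append(f"- candidates: {m['n_candidates']}")
        lines.append(f"- significant at 0.05: {m['n_significant']}")
        if "n_lower_p_than_reference" in m:
            lines.append(
                f"- lower p than reference index: {m['n_lower_p_than_reference']}"
            )
        lines.append("")
    return "\n".join(lines)
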