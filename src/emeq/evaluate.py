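"""Validation of the combined equation and the end-to-end pipeline.

Leave-one-diet-out cross-validation refits the combining model with one diet
held out and predicts that diet's records as the fixed-effect part plus each
equation's training-estimated random intercept (the equations are the same
groups across diets, so their intercepts transfer). Per-diet skill is
``R^2 = 1 - SSE/SST`` over the held-out records, which credits the model for
explaining the between-equation disagreement within the diet.

The leave-one-equation-out sensitivity analysis removes each source equation
in turn, refits, and tabulates the back-transformed raw coefficients; narrow
ranges mean no single published equation drives the combined equation.

:func:`run_pipeline` chains every stage (load -> complete -> predict ->
screen -> fit candidates -> select -> back-transform -> CV -> sensitivity)
into a reproducible run directory with a manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import __version__
from .combine import (
    CombinedEquation,
    CombinedEquationResults,
    ScreenResult,
    SelectionResult,
    back_transform,
    comparison_table,
    fit_all_candidates,
    fit_mixed,
    screen_collinearity,
    select_model,
    vif,
)
from .diets import diets_to_frame, load_diets, packaged_diets
from .equations import (
    ExtremesTable,
    PredictionSet,
    apply_all,
    diet_extremes,
    load_registry,
    packaged_registry,
)
from .synth import CompletionConfig, complete_diets

__all__ = [
    "REFERENCE_COMBINED_EQUATION",
    "predict_combined",
    "reference_extremes",
    "CVReport",
    "loo_diet_cv",
    "SensitivityReport",
    "sensitivity_loo_equation",
    "PipelineConfig",
    "RunResult",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

#: The published combined equation: CH4 (g/kg DM) = 0.33*ME + 0.31*NDF + 3.47.
REFERENCE_COMBINED_EQUATION = CombinedEquation(
    intercept=3.47,
    coefficients={"ME": 0.33, "NDF": 0.31},
    model_id=1,
    provenance="published-reference",
)


def predict_combined(
    me_conc: float,
    ndf_pct: float,
    eq: CombinedEquation | None = None,
) -> float:
    """Methane prediction (g CH4/kg DM) from ME (MJ/kg DM) and NDF (% DM).

    Uses the packaged reference coefficients (0.33, 0.31, 3.47) unless a
    fitted :class:`CombinedEquation` is supplied.
    """
    for name, v in (("me_conc", me_conc), ("ndf_pct", ndf_pct)):
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be finite and non-negative, got {v}")
    eq = eq or REFERENCE_COMBINED_EQUATION
    return eq.predict(ME=me_conc, NDF=ndf_pct)


def reference_extremes() -> pd.DataFrame:
    """Published per-diet min/max emissions envelope (g CH4/kg DM)."""
    with resources.as_file(
        resources.files("emeq.data").joinpath("reference_extremes.csv")
    ) as p:
        df = pd.read_csv(p)
    df["diet_id"] = df["diet_id"].astype(str)
    return df


@dataclass(frozen=True)
class CVReport:
    """Leave-one-diet-out cross-validation results.

    ``per_diet`` has one row per held-out diet (r2, rmse, converged);
    aggregates are recomputed over the converged rows only.
    """

    per_diet: pd.DataFrame
    mean_r2: float
    median_r2: float
    min_r2: float
    max_r2: float
    mean_rmse: float
    min_rmse: float
    max_rmse: float

    @staticmethod
    def from_rows(per_diet: pd.DataFrame) -> "CVReport":
        ok = per_diet[per_diet["converged"]]
        return CVReport(
            per_diet=per_diet,
            mean_r2=float(ok["r2"].mean()),
            median_r2=float(ok["r2"].median()),
            min_r2=float(ok["r2"].min()),
            max_r2=float(ok["r2"].max()),
            mean_rmse=float(ok["rmse"].mean()),
            min_rmse=float(ok["rmse"].min()),
            max_rmse=float(ok["rmse"].max()),
        )


def loo_diet_cv(
    preds: PredictionSet,
    predictors: Sequence[str] = ("ME", "NDF"),
) -> CVReport:
    """Leave-one-diet-out cross-validation of the combining model.

    For each diet: refit on the remaining diets, predict the held-out
    records as fixed effects plus the training random intercept of each
    equation, then score ``R^2 = 1 - SSE/SST`` and RMSE over those records.
    """
    if preds.n_diets < 3:
        raise ValueError("leave-one-diet-out CV needs at least 3 diets")
    rows = []
    for diet_id in preds.diet_ids:
        train = preds.drop_diet(diet_id)
        test = preds.only_diet(diet_id)
        try:
            fit = fit_mixed(train, predictors)
        except Exception as exc:
            warnings.warn(f"CV refit failed for held-out diet {diet_id}: {exc}")
            rows.append(
                {"diet_id": diet_id, "r2": np.nan, "rmse": np.nan, "converged": False}
            )
            continue
        eq = fit.to_equation()
        u = fit.random_effects
        yhat = eq.predict_frame(test) + np.array(
            [u.get(e, 0.0) for e in test.frame["eq_id"]]
        )
        y = test.frame["ch4_g_per_kg_dm"].to_numpy(dtype=float)
        sse = float(np.sum((y - yhat) ** 2))
        sst = float(np.sum((y - y.mean()) ** 2))
        if sst == 0:
            warnings.warn(
                f"held-out diet {diet_id} has zero between-equation spread; "
                "R^2 undefined"
            )
            r2 = np.nan
        else:
            r2 = 1.0 - sse / sst
        rows.append(
            {
                "diet_id": diet_id,
                "r2": r2,
                "rmse": float(np.sqrt(np.mean((y - yhat) ** 2))),
                "converged": fit.converged,
            }
        )
    return CVReport.from_rows(pd.DataFrame(rows))


@dataclass(frozen=True)
class SensitivityReport:
    """Leave-one-equation-out stability of the raw-scale coefficients.

    ``per_equation`` has one row per removed equation with the refitted raw
    coefficients; ``ranges`` holds each predictor's (min, max) over removals
    and ``full_data`` the coefficients with nothing removed.
    """

    per_equation: pd.DataFrame
    ranges: dict[str, tuple[float, float]]
    full_data: dict[str, float]


def sensitivity_loo_equation(
    preds: PredictionSet,
    predictors: Sequence[str] = ("ME", "NDF"),
) -> SensitivityReport:
    """Remove each equation in turn, refit, and tabulate raw coefficients."""
    if preds.n_equations < 3:
        raise ValueError("sensitivity analysis needs at least 3 equations")
    full = fit_mixed(preds, predictors).to_equation()
    rows = []
    for eq_id in preds.eq_ids:
        fit = fit_mixed(preds.drop_equation(eq_id), predictors)
        eq = fit.to_equation()
        row = {"removed_eq_id": eq_id, "intercept": eq.intercept}
        row.update(eq.coefficients)
        rows.append(row)
    per_eq = pd.DataFrame(rows)
    ranges = {
        p: (float(per_eq[p].min()), float(per_eq[p].max()))
        for p in ("intercept", *predictors)
    }
    full_data = {"intercept": full.intercept, **full.coefficients}
    return SensitivityReport(per_equation=per_eq, ranges=ranges, full_data=full_data)


class PipelineConfig(BaseModel):
    """Configuration of an end-to-end run."""

    model_config = ConfigDict(frozen=True)

    diets_csv: str | None = None  # None -> packaged 15-diet fixture
    registry_path: str | None = None  # None -> packaged registry
    completion: CompletionConfig = CompletionConfig()
    model: int | Literal["auto"] = "auto"
    include_dry: bool = True
    seed: int | None = None  # overrides completion.seed when set

    def resolved_completion(self) -> CompletionConfig:
        if self.seed is None:
            return self.completion
        return self.completion.model_copy(update={"seed": self.seed})


@dataclass
class RunResult:
    """In-memory artefacts of a pipeline run."""

    config: PipelineConfig
    predictions: PredictionSet
    extremes: ExtremesTable
    screen: ScreenResult
    fits: list[CombinedEquationResults]
    selection: SelectionResult
    equation: CombinedEquation
    vif: dict[str, float]
    cv: CVReport
    sensitivity: SensitivityReport
    manifest: dict


def run_pipeline(
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> RunResult:
    """Execute the full chain and (optionally) write a run directory.

    Stages: load diets -> complete -> apply registry -> per-diet extremes ->
    collinearity screen -> fit the 12 candidates -> select -> back-transform
    -> VIF -> leave-one-diet-out CV -> leave-one-equation-out sensitivity.
    Any stage failure is re-raised with the stage name.
    """
    config = config or PipelineConfig()
    stage = "load diets"
    try:
        diets = (
            load_diets(config.diets_csv) if config.diets_csv else packaged_diets()
        )
        if not config.include_dry:
            diets = [d for d in diets if d.cohort != "dry"]
        stage = "complete diets"
        completion = config.resolved_completion()
        completed = complete_diets(diets, completion)
        stage = "load registry"
        registry = (
            load_registry(config.registry_path)
            if config.registry_path
            else packaged_registry()
        )
        stage = "apply equations"
        preds = apply_all(registry, completed)
        stage = "diet extremes"
        extremes = diet_extremes(preds)
        stage = "collinearity screen"
        screen = screen_collinearity(completed)
        stage = "fit candidate models"
        fits = fit_all_candidates(preds)
        stage = "model selection"
        if config.model == "auto":
            selection = select_model(fits)
        else:
            chosen = next(f for f in fits if f.model_id == config.model)
            selection = SelectionResult(
                model_id=chosen.model_id,
                results=chosen,
                all_significant=chosen.all_slopes_significant,
                rationale=f"model {config.model} forced by configuration"
                + (
                    ""
                    if chosen.all_slopes_significant
                    else "; warning: not all slopes significant (|t| <= 2)"
                ),
                table=comparison_table(fits),
            )
        stage = "back-transform"
        equation = back_transform(selection.results)
        stage = "variance inflation"
        vifs = vif(preds, selection.results.predictors)
        stage = "cross-validation"
        cv = loo_diet_cv(preds, selection.results.predictors)
        stage = "sensitivity"
        sens = sensitivity_loo_equation(preds, selection.results.predictors)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    cfg_json = config.model_dump_json()
    manifest = {
        "package_version": __version__,
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": completion.seed,
        "n_diets": len(completed),
        "n_equations": len(registry),
        "n_prediction_records": len(preds),
        "selected_model": selection.model_id,
        "all_slopes_significant": selection.all_significant,
        "selection_rationale": selection.rationale,
        "combined_equation": {
            "intercept": equation.intercept,
            "coefficients": equation.coefficients,
        },
        "r2": selection.results.r2,
        "rmse": selection.results.rmse,
        "residual_variance": selection.results.var_resid,
        "between_equation_variance": selection.results.var_equation,
        "between_equation_sd": selection.results.sigma_equation,
        "vif": vifs,
        "cv": {
            "mean_r2": cv.mean_r2,
            "median_r2": cv.median_r2,
            "min_r2": cv.min_r2,
            "max_r2": cv.max_r2,
            "mean_rmse": cv.mean_rmse,
            "min_rmse": cv.min_rmse,
            "max_rmse": cv.max_rmse,
        },
        "sensitivity_ranges": {k: list(v) for k, v in sens.ranges.items()},
    }
    result = RunResult(
        config=config,
        predictions=preds,
        extremes=extremes,
        screen=screen,
        fits=fits,
        selection=selection,
        equation=equation,
        vif=vifs,
        cv=cv,
        sensitivity=sens,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_run_dir(result, completed, Path(out_dir))
    return result


def _write_run_dir(result: RunResult, completed, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    diets_to_frame(completed).to_csv(out / "diets_completed.csv", index=False)
    result.predictions.frame.to_csv(out / "predictions.csv", index=False)
    result.extremes.per_diet.to_csv(out / "extremes_per_diet.csv", index=False)
    result.selection.table.to_csv(out / "model_comparison.csv", index=False)
    result.cv.per_diet.to_csv(out / "cv_per_diet.csv", index=False)
    result.sensitivity.per_equation.to_csv(out / "sensitivity.csv", index=False)
    re_rows = pd.DataFrame(
        {
            "eq_id": list(result.selection.results.random_effects),
            "random_intercept": list(result.selection.results.random_effects.values()),
        }
    )
    re_rows.to_csv(out / "random_effects.csv", index=False)
    with open(out / "combined_equation.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "intercept": result.equation.intercept,
                "coefficients": result.equation.coefficients,
                "model_id": result.equation.model_id,
                "provenance": result.equation.provenance,
            },
            fh,
            indent=2,
        )
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(result.manifest, fh, indent=2)
    with open(out / "summary.txt", "w", encoding="utf-8") as fh:
        fh.write(result.selection.results.summary() + "\n")
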