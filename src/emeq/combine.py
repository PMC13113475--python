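"""Derivation of the combined methane prediction equation.

The long equation x diet prediction table is treated as clustered data:
predictions are nested within their source equation, so the combining model
is a linear mixed model with a random intercept per equation,

    y_ij = b0 + sum_j b_j X_ij + u_i + e_ij,

with ``u_i ~ N(0, sigma_equation^2)`` capturing between-equation
heterogeneity and ``e_ij ~ N(0, sigma^2)`` the residual. Predictors are
centred and scaled over the long table before fitting (the response is
not), and the fitted standardized coefficients are back-transformed to the
raw measurement units:

    b_j,raw = b_j* / SD(X_j)
    b_0,raw = b_0* - sum_j b_j* mean(X_j) / SD(X_j).

Candidate predictor subsets are screened for collinearity (Pearson
correlation across diets; variance inflation factors on the fitted design)
and compared on R^2, RMSE and residual variance; slopes are called
significant when |t| > 2.

The statsmodels-style surface is :class:`CombinedEquationModel` (model,
built from a prediction set) and :class:`CombinedEquationResults` (fit);
module-level functions mirror the pipeline steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from .diets import CompletedDiet, DietProfile, diets_to_frame
from .equations import PredictionSet
from .lmm import RandomInterceptLMM, RandomInterceptLMMResults

__all__ = [
    "PREDICTOR_COLUMNS",
    "ScalingParams",
    "standardize",
    "screen_collinearity",
    "ScreenResult",
    "candidate_models",
    "CandidateModel",
    "CombinedEquationModel",
    "CombinedEquationResults",
    "MixedFitResult",
    "CombinedEquation",
    "fit_mixed",
    "fit_all_candidates",
    "back_transform",
    "vif",
    "select_model",
    "SelectionResult",
    "T_SIGNIFICANCE",
]

#: Column in the long prediction table holding each predictor.
PREDICTOR_COLUMNS: dict[str, str] = {
    "ME": "me_mj_kg",
    "GE": "ge_mj_kg",
    "NDF": "ndf_pct",
    "ADF": "adf_pct",
    "CP": "cp_pct",
    "EE": "ee_pct",
    "FA": "fa_pct",
    "FORAGE": "forage_pct",
    "ASH": "ash_pct",
}

RESPONSE_COLUMN = "ch4_g_per_kg_dm"

#: Slope significance rule: |t| greater than this.
T_SIGNIFICANCE = 2.0

#: Preference order when one variable of a correlated cluster is retained.
DEFAULT_PRIORITY = ("NDF", "ME", "GE", "CP", "EE", "FA", "ADF", "FORAGE", "ASH")


class ZeroVarianceError(ValueError):
    """A predictor has no variance over the table being standardized."""


class CollinearityError(ValueError):
    """Predictors are exactly collinear (infinite VIF)."""


def _predictor_frame(
    data: PredictionSet | pd.DataFrame | Sequence[DietProfile],
    predictors: Sequence[str],
) -> pd.DataFrame:
    """Extract predictor columns (named by variable) from any supported input."""
    if isinstance(data, PredictionSet):
        frame = data.frame
    elif isinstance(data, pd.DataFrame):
        frame = data
    else:
        frame = diets_to_frame(list(data))
    out = {}
    for name in predictors:
        if name in frame.columns:
            out[name] = frame[name].to_numpy(dtype=float)
            continue
        col = PREDICTOR_COLUMNS.get(name)
        if col is None or col not in frame.columns:
            raise KeyError(f"predictor {name!r} not resolvable from the input table")
        out[name] = frame[col].to_numpy(dtype=float)
    return pd.DataFrame(out)


@dataclass(frozen=True)
class ScalingParams:
    """Per-predictor mean and sample SD used for standardization."""

    means: dict[str, float]
    sds: dict[str, float]

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(
            {c: (X[c] - self.means[c]) / self.sds[c] for c in X.columns}
        )

    def invert(self, Xstd: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(
            {c: Xstd[c] * self.sds[c] + self.means[c] for c in Xstd.columns}
        )


def standardize(
    data: PredictionSet | pd.DataFrame | Sequence[DietProfile],
    predictors: Sequence[str],
) -> tuple[pd.DataFrame, ScalingParams]:
    """Centre and scale predictors over the long table.

    Uses the sample (n-1) standard deviation of each predictor over all rows
    of the table as fitted, so repeated diet rows count once per prediction
    record. The response is never standardized.
    """
    X = _predictor_frame(data, predictors)
    means, sds = {}, {}
    for c in X.columns:
        sd = float(X[c].std(ddof=1))
        if not sd > 0:
            raise ZeroVarianceError(f"predictor {c!r} has zero variance")
        means[c] = float(X[c].mean())
        sds[c] = sd
    scaling = ScalingParams(means=means, sds=sds)
    return scaling.transform(X), scaling


@dataclass(frozen=True)
class ScreenResult:
    """Correlation screen over diets: clusters of interchangeable variables."""

    correlations: pd.DataFrame
    clusters: list[tuple[str, ...]]
    retained: tuple[str, ...]
    dropped: tuple[str, ...]
    threshold: float


def screen_collinearity(
    diets: Sequence[DietProfile] | pd.DataFrame,
    variables: Sequence[str] = ("ME", "GE", "NDF", "ADF", "CP", "EE", "FA"),
    threshold: float = 0.75,
    priority: Sequence[str] = DEFAULT_PRIORITY,
) -> ScreenResult:
    """Group variables whose pairwise |Pearson r| across diets exceeds a cutoff.

    One representative is retained per cluster, chosen by ``priority`` order
    (default keeps NDF over ADF and ME over GE). Requires at least 3 diets;
    a constant column raises :class:`ZeroVarianceError`.
    """
    X = _predictor_frame(diets, variables)
    if len(X) < 3:
        raise ValueError("need at least 3 diets for a correlation screen")
    for c in X.columns:
        if not X[c].std(ddof=1) > 0:
            raise ZeroVarianceError(f"variable {c!r} is constant across diets")
    corr = X.corr(method="pearson")
    names = list(X.columns)
    parent = {v: v for v in names}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if abs(corr.loc[a, b]) > threshold:
                parent[find(a)] = find(b)
    groups: dict[str, list[str]] = {}
    for v in names:
        groups.setdefault(find(v), []).append(v)

    def rank(v: str) -> tuple[int, int]:
        return (
            priority.index(v) if v in priority else len(priority),
            names.index(v),
        )

    clusters, retained, dropped = [], [], []
    for members in groups.values():
        members = sorted(members, key=rank)
        rep = members[0]
        retained.append(rep)
        if len(members) > 1:
            clusters.append(tuple(members))
            dropped.extend(members[1:])
    retained.sort(key=rank)
    return ScreenResult(
        correlations=corr,
        clusters=clusters,
        retained=tuple(retained),
        dropped=tuple(dropped),
        threshold=threshold,
    )


@dataclass(frozen=True)
class CandidateModel:
    model_id: int
    predictors: tuple[str, ...]


#: The twelve candidate predictor combinations compared for the combined
#: equation. Every combination contains NDF; all but 3 and 10 contain an
#: energy proxy (GE or ME).
_CANDIDATES: tuple[tuple[int, tuple[str, ...]], ...] = (
    (1, ("ME", "NDF")),
    (2, ("GE", "NDF")),
    (3, ("NDF", "EE")),
    (4, ("ME", "NDF", "FA")),
    (5, ("ME", "NDF", "EE")),
    (6, ("ME", "CP", "NDF")),
    (7, ("GE", "CP", "NDF")),
    (8, ("GE", "NDF", "FA")),
    (9, ("GE", "NDF", "EE")),
    (10, ("CP", "NDF", "FA", "EE")),
    (11, ("GE", "CP", "NDF", "FA", "EE")),
    (12, ("ME", "CP", "NDF", "FA", "EE")),
)


def candidate_models() -> list[CandidateModel]:
    """The twelve candidate predictor combinations, in model-id order."""
    return [CandidateModel(mid, preds) for mid, preds in _CANDIDATES]


class CombinedEquation(BaseModel):
    """Raw-scale combined prediction equation.

    Response is g CH4/kg DM; ME and GE enter in MJ/kg DM and the composition
    variables in % of DM. Prediction is ``intercept + sum(coef * value)``.
    """

    model_config = ConfigDict(frozen=True)

    intercept: float
    coefficients: dict[str, float]
    model_id: int | None = None
    provenance: str = "fitted"

    @property
    def predictors(self) -> tuple[str, ...]:
        return tuple(self.coefficients)

    def predict(self, **values: float) -> float:
        missing = [p for p in self.coefficients if p not in values]
        if missing:
            raise ValueError(f"missing predictor value(s): {missing}")
        return self.intercept + sum(
            coef * float(values[name]) for name, coef in self.coefficients.items()
        )

    def predict_frame(self, data: PredictionSet | pd.DataFrame) -> np.ndarray:
        X = _predictor_frame(data, list(self.coefficients))
        out = np.full(len(X), self.intercept, dtype=float)
        for name, coef in self.coefficients.items():
            out += coef * X[name].to_numpy()
        return out


class CombinedEquationModel:
    """Random-intercept combining model over a prediction set.

    Parameters
    ----------
    preds : PredictionSet
        Long equation x diet table (response ``ch4_g_per_kg_dm``).
    predictors : sequence of str
        Variable names among ``PREDICTOR_COLUMNS`` (e.g. ``("ME", "NDF")``).
    model_id : int, optional
        Candidate-model label carried through to reports.
    standardize : bool
        Centre/scale predictors before fitting (default). The fitted
        coefficients are back-transformable to raw units either way.
    """

    def __init__(
        self,
        preds: PredictionSet,
        predictors: Sequence[str] = ("ME", "NDF"),
        model_id: int | None = None,
        standardize: bool = True,
    ) -> None:
        if preds.n_equations < 2 or preds.n_diets < 2:
            raise ValueError("need at least 2 equations and 2 diets to fit")
        self.preds = preds
        self.predictors = tuple(predictors)
        self.model_id = model_id
        self._standardize = standardize

    @classmethod
    def from_predictions(
        cls, preds: PredictionSet, predictors: Sequence[str] = ("ME", "NDF"), **kw
    ) -> "CombinedEquationModel":
        return cls(preds, predictors, **kw)

    def fit(self) -> "CombinedEquationResults":
        frame = self.preds.frame
        y = frame[RESPONSE_COLUMN].to_numpy(dtype=float)
        if self._standardize:
            X, scaling = standardize(self.preds, self.predictors)
        else:
            X = _predictor_frame(self.preds, self.predictors)
            scaling = None
        design = X.copy()
        design.insert(0, "intercept", 1.0)
        lmm = RandomInterceptLMM(y, design, frame["eq_id"].to_numpy())
        res = lmm.fit()
        return CombinedEquationResults(model=self, _lmm=res, scaling=scaling)


@dataclass
class CombinedEquationResults:
    """Fit of the combining model.

    Coefficients are on the standardized-predictor scale when the model was
    standardized (the response never is); :meth:`to_equation` returns the
    raw-scale :class:`CombinedEquation`. ``r2`` is the squared Pearson
    correlation between observations and fitted values including the random
    intercepts; ``rmse`` is the root mean squared residual on the same
    fitted values; ``var_resid`` is the REML residual variance.
    """

    model: CombinedEquationModel
    _lmm: RandomInterceptLMMResults
    scaling: ScalingParams | None

    # -- estimates --------------------------------------------------------

    @property
    def model_id(self) -> int | None:
        return self.model.model_id

    @property
    def predictors(self) -> tuple[str, ...]:
        return self.model.predictors

    @property
    def params(self) -> pd.Series:
        return self._lmm.params

    @property
    def bse(self) -> pd.Series:
        return self._lmm.bse

    @property
    def tvalues(self) -> pd.Series:
        return self._lmm.tvalues

    @property
    def var_equation(self) -> float:
        return self._lmm.var_group

    @property
    def sigma_equation(self) -> float:
        return math.sqrt(self._lmm.var_group)

    @property
    def var_resid(self) -> float:
        return self._lmm.var_resid

    @property
    def random_effects(self) -> dict:
        return self._lmm.random_effects

    @property
    def fittedvalues(self) -> np.ndarray:
        return self._lmm.fittedvalues

    @property
    def resid(self) -> np.ndarray:
        return self._lmm.resid

    @property
    def converged(self) -> bool:
        return self._lmm.converged

    @property
    def boundary(self) -> bool:
        return self._lmm.boundary

    @property
    def nobs(self) -> int:
        return self._lmm.model.nobs

    # -- diagnostics ------------------------------------------------------

    @property
    def r2(self) -> float:
        y = self._lmm.model.endog
        f = self.fittedvalues
        if np.allclose(f, f[0]) or np.allclose(y, y[0]):
            return float("nan")
        return float(np.corrcoef(y, f)[0, 1] ** 2)

    @property
    def rmse(self) -> float:
        return float(np.sqrt(np.mean(self.resid**2)))

    @property
    def all_slopes_significant(self) -> bool:
        slopes = self.tvalues.drop("intercept")
        return bool((slopes.abs() > T_SIGNIFICANCE).all())

    def significance_table(self) -> pd.DataFrame:
        tab = pd.DataFrame(
            {
                "estimate": self.params,
                "std_error": self.bse,
                "t_value": self.tvalues,
            }
        )
        tab["significant"] = tab["t_value"].abs() > T_SIGNIFICANCE
        tab.loc["intercept", "significant"] = True
        return tab

    # -- back-transformation ----------------------------------------------

    def to_equation(self) -> CombinedEquation:
        """Raw-scale equation (back-transforming if the fit was standardized)."""
        if self.scaling is None:
            coefs = {p: float(self.params[p]) for p in self.predictors}
            intercept = float(self.params["intercept"])
            prov = "fitted-raw"
        else:
            coefs = {
                p: float(self.params[p]) / self.scaling.sds[p]
                for p in self.predictors
            }
            intercept = float(self.params["intercept"]) - sum(
                float(self.params[p]) * self.scaling.means[p] / self.scaling.sds[p]
                for p in self.predictors
            )
            prov = "fitted-standardized-backtransformed"
        return CombinedEquation(
            intercept=intercept,
            coefficients=coefs,
            model_id=self.model_id,
            provenance=prov,
        )

    def summary(self) -> str:
        head = f"Combined methane equation fit (model {self.model_id})" \
            if self.model_id else "Combined methane equation fit"
        lines = [
            head,
            f"  predictors: {' + '.join(self.predictors)}"
            + ("  (standardized)" if self.scaling else "  (raw scale)"),
            f"  R^2 = {self.r2:.4f}   RMSE = {self.rmse:.4f} g CH4/kg DM   "
            f"residual variance = {self.var_resid:.4f}",
            f"  between-equation variance = {self.var_equation:.4f} "
            f"(SD = {self.sigma_equation:.4f})",
            "",
            self._lmm.summary(),
        ]
        eq = self.to_equation()
        terms = " + ".join(
            f"{c:.4f}*{p}" for p, c in eq.coefficients.items()
        )
        lines.append("")
        lines.append(f"  raw scale: CH4 (g/kg DM) = {terms} + {eq.intercept:.4f}")
        return "\n".join(lines)


#: Spec-facing alias: the fit result of the mixed combining model.
MixedFitResult = CombinedEquationResults


def fit_mixed(
    preds: PredictionSet,
    predictors: Sequence[str] = ("ME", "NDF"),
    model_id: int | None = None,
    standardize: bool = True,
) -> CombinedEquationResults:
    """REML fit of the random-intercept combining model (see module docs)."""
    return CombinedEquationModel(
        preds, predictors, model_id=model_id, standardize=standardize
    ).fit()


def fit_all_candidates(preds: PredictionSet) -> list[CombinedEquationResults]:
    """Fit each of the twelve candidate predictor combinations."""
    return [
        fit_mixed(preds, cand.predictors, model_id=cand.model_id)
        for cand in candidate_models()
    ]


def back_transform(fit: CombinedEquationResults) -> CombinedEquation:
    """Raw-scale coefficients from a standardized fit.

    Slopes are divided by each predictor's sample SD; the intercept
    reintroduces the predictor means (see module docstring).
    """
    if not fit.converged:
        raise ValueError("cannot back-transform a non-converged fit")
    if fit.scaling is None:
        raise ValueError("fit carries no scaling parameters (raw-scale fit)")
    return fit.to_equation()


def vif(
    design: PredictionSet | pd.DataFrame | Sequence[DietProfile],
    predictors: Sequence[str],
) -> dict[str, float]:
    """Variance inflation factors: ``VIF_j = 1 / (1 - R^2_j)``.

    ``R^2_j`` comes from regressing predictor j on the remaining predictors
    (with intercept). Exact collinearity raises :class:`CollinearityError`.
    """
    predictors = list(predictors)
    if len(predictors) < 2:
        raise ValueError("VIF needs at least 2 predictors")
    X = _predictor_frame(design, predictors)
    out = {}
    for j, name in enumerate(predictors):
        others = [p for p in predictors if p != name]
        A = np.column_stack([np.ones(len(X))] + [X[p].to_numpy() for p in others])
        yj = X[name].to_numpy()
        coef, *_ = np.linalg.lstsq(A, yj, rcond=None)
        resid = yj - A @ coef
        sst = float(np.sum((yj - yj.mean()) ** 2))
        if sst == 0:
            raise ZeroVarianceError(f"predictor {name!r} is constant")
        r2 = 1.0 - float(np.sum(resid**2)) / sst
        if r2 >= 1.0 - 1e-12:
            raise CollinearityError(
                f"predictor {name!r} is exactly collinear with {others}"
            )
        out[name] = 1.0 / (1.0 - r2)
    return out


@dataclass(frozen=True)
class SelectionResult:
    """Choice among the candidate fits plus the full comparison table."""

    model_id: int
    results: CombinedEquationResults
    all_significant: bool
    rationale: str
    table: pd.DataFrame


def comparison_table(fits: Sequence[CombinedEquationResults]) -> pd.DataFrame:
    rows = []
    for f in fits:
        rows.append(
            {
                "model_id": f.model_id,
                "predictors": "+".join(f.predictors),
                "n_predictors": len(f.predictors),
                "r2": f.r2,
                "rmse": f.rmse,
                "residual_variance": f.var_resid,
                "var_equation": f.var_equation,
                "all_slopes_significant": f.all_slopes_significant,
                "converged": f.converged,
            }
        )
    return pd.DataFrame(rows)


def select_model(
    fits: Sequence[CombinedEquationResults],
    rule: str = "parsimony",
) -> SelectionResult:
    """Pick the combined-equation model from candidate fits.

    Default rule: among converged fits whose every slope is significant
    (|t| > 2), prefer the fewest predictors, break ties by lower RMSE, then
    prefer ME over GE as the energy proxy. If no candidate is fully
    significant, the best-RMSE converged fit is returned flagged as such.
    """
    if rule != "parsimony":
        raise ValueError(f"unknown selection rule: {rule!r}")
    converged = [f for f in fits if f.converged]
    if not converged:
        raise ValueError("no converged fits to select from")
    table = comparison_table(fits)

    def key(f: CombinedEquationResults):
        energy_rank = 0 if "ME" in f.predictors else (1 if "GE" in f.predictors else 2)
        return (
            len(f.predictors),
            round(f.rmse, 6),
            energy_rank,
            f.model_id if f.model_id is not None else 0,
        )

    significant = [f for f in converged if f.all_slopes_significant]
    if significant:
        chosen = min(significant, key=key)
        rationale = (
            f"model {chosen.model_id} ({'+'.join(chosen.predictors)}): fewest "
            f"predictors among the {len(significant)} fully significant "
            f"candidates; ties broken by RMSE then ME-over-GE preference"
        )
        all_sig = True
    else:
        chosen = min(converged, key=lambda f: f.rmse)
        rationale = (
            f"no candidate had all slopes significant (|t| > {T_SIGNIFICANCE}); "
            f"falling back to lowest RMSE: model {chosen.model_id}"
        )
        all_sig = False
    return SelectionResult(
        model_id=chosen.model_id,
        results=chosen,
        all_significant=all_sig,
        rationale=rationale,
        table=table,
    )
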