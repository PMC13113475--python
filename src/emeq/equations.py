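"""Unit-aware registry of published enteric methane prediction equations.

Each record encodes one published formula declaratively: an intercept, a list
of (coefficient, variable, unit) terms, an overall shape (plain linear, or
linear multiplied by DMI) and an output unit. Records whose sources report
methane as energy (MJ/day) are converted to mass with the 55.65 kJ/g CH4
energy content, i.e. division by 0.05565 MJ per gram.

Applying the registry to a set of completed diets produces the long
equation x diet prediction table (one row per cell, response in both
g CH4/day and g CH4/kg DM) that the combining model is fitted to.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from .diets import CompletedDiet

__all__ = [
    "ENERGY_MJ_PER_G_CH4",
    "EquationRecord",
    "EquationTerm",
    "PredictionSet",
    "RegistryMeta",
    "RegistrySchemaError",
    "EvaluationError",
    "load_registry",
    "packaged_registry",
    "packaged_registry_meta",
    "energy_to_mass",
    "evaluate_daily",
    "apply_all",
    "diet_extremes",
    "ExtremesTable",
]

#: Energy content of methane: 55.65 kJ/g, so 0.05565 MJ is one gram of CH4.
ENERGY_MJ_PER_G_CH4 = 0.05565

Variable = Literal["DMI", "MEI", "NDF", "ADF", "EE", "FA", "CP", "ASH", "FORAGE"]
Unit = Literal["kg_dm_per_day", "mj_per_day", "pct_dm", "kg_per_day_intake"]

#: Diet attribute holding each variable's concentration (% of DM).
_PCT_ATTR = {
    "NDF": "ndf_pct",
    "ADF": "adf_pct",
    "EE": "ee_pct",
    "FA": "fa_pct",
    "CP": "cp_pct",
    "ASH": "ash_pct",
    "FORAGE": "forage_pct",
}


class RegistrySchemaError(ValueError):
    """The registry file contains an invalid or duplicate record."""


class EvaluationError(ValueError):
    """An equation references a variable the diet cannot resolve."""


class EquationTerm(BaseModel):
    model_config = ConfigDict(frozen=True)

    coef: float
    var: Variable
    unit: Unit
    #: optional per-term energy-to-mass divisor (used when a source converts
    #: only part of the published expression to grams).
    energy_divisor: float | None = None


class EquationRecord(BaseModel):
    """One published methane prediction formula."""

    model_config = ConfigDict(frozen=True)

    eq_id: str
    source: str
    shape: Literal["LINEAR", "LINEAR_TIMES_DMI"]
    output_unit: Literal["MJ_PER_DAY", "G_PER_DAY"]
    intercept: float
    terms: tuple[EquationTerm, ...]
    unit_uncertain: bool = False


class RegistryMeta(BaseModel):
    """Bookkeeping for the literature selection cascade behind the registry."""

    model_config = ConfigDict(frozen=True)

    n_equations: int
    n_sources: int
    selection_cascade: dict[str, int]


def energy_to_mass(e: float) -> float:
    """Convert methane energy (MJ/day) to mass (g/day): ``e / 0.05565``."""
    return e / ENERGY_MJ_PER_G_CH4


def _resolve(term: EquationTerm, diet: CompletedDiet, eq_id: str) -> float:
    if term.unit == "kg_dm_per_day":
        if term.var != "DMI":
            raise EvaluationError(f"{eq_id}: unit kg_dm_per_day requires DMI")
        return diet.dmi
    if term.unit == "mj_per_day":
        if term.var != "MEI":
            raise EvaluationError(f"{eq_id}: unit mj_per_day requires MEI")
        return diet.mei
    if term.var in ("DMI", "MEI"):
        raise EvaluationError(
            f"{eq_id}: variable {term.var} cannot take unit {term.unit}"
        )
    pct = getattr(diet, _PCT_ATTR[term.var])
    if term.unit == "pct_dm":
        return pct
    # kg_per_day_intake: nutrient mass eaten per day
    return pct / 100.0 * diet.dmi


def evaluate_daily(eq: EquationRecord, diet: CompletedDiet) -> float:
    """Evaluate one equation for one diet, in g CH4/day.

    MJ/day records are converted with :func:`energy_to_mass`. A negative
    prediction is returned as-is with a warning (clamping would bias the
    ensemble statistics).
    """
    total = eq.intercept
    for term in eq.terms:
        contrib = term.coef * _resolve(term, diet, eq.eq_id)
        if term.energy_divisor is not None:
            contrib /= term.energy_divisor
        total += contrib
    if eq.shape == "LINEAR_TIMES_DMI":
        total *= diet.dmi
    if eq.output_unit == "MJ_PER_DAY":
        total = energy_to_mass(total)
    if total < 0:
        warnings.warn(
            f"{eq.eq_id} on diet {diet.diet_id}: negative prediction "
            f"({total:.2f} g/day)",
            stacklevel=2,
        )
    return total


#: Columns of the long prediction table.
PREDICTION_COLUMNS = (
    "eq_id",
    "diet_id",
    "ch4_g_per_day",
    "ch4_g_per_kg_dm",
    "dmi_kg_d",
    "me_mj_kg",
    "ge_mj_kg",
    "ndf_pct",
    "adf_pct",
    "cp_pct",
    "ee_pct",
    "fa_pct",
    "forage_pct",
    "ash_pct",
)


@dataclass
class PredictionSet:
    """Long equation x diet table of methane predictions.

    ``frame`` has one row per (equation, diet) cell with the response in
    g CH4/day and g CH4/kg DM plus every candidate predictor. For simulated
    sets, ``true_random_effects`` records the equation-level intercepts the
    generator used, so recovery can be checked against the truth.
    """

    frame: pd.DataFrame
    true_random_effects: dict[str, float] | None = None
    true_params: dict[str, float] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in PREDICTION_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"prediction table missing columns: {missing}")

    @property
    def eq_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["eq_id"]))

    @property
    def diet_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["diet_id"]))

    @property
    def n_equations(self) -> int:
        return len(self.eq_ids)

    @property
    def n_diets(self) -> int:
        return len(self.diet_ids)

    def __len__(self) -> int:
        return len(self.frame)

    def drop_diet(self, diet_id: str) -> "PredictionSet":
        return PredictionSet(
            self.frame[self.frame["diet_id"] != diet_id].reset_index(drop=True),
            true_random_effects=self.true_random_effects,
            true_params=self.true_params,
        )

    def only_diet(self, diet_id: str) -> "PredictionSet":
        return PredictionSet(
            self.frame[self.frame["diet_id"] == diet_id].reset_index(drop=True),
            true_random_effects=self.true_random_effects,
            true_params=self.true_params,
        )

    def drop_equation(self, eq_id: str) -> "PredictionSet":
        return PredictionSet(
            self.frame[self.frame["eq_id"] != eq_id].reset_index(drop=True),
            true_random_effects=self.true_random_effects,
            true_params=self.true_params,
        )


def load_registry(path: str | Path) -> list[EquationRecord]:
    """Parse and validate an equation registry file."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    records = []
    seen = set()
    for raw in doc.get("equations", []):
        try:
            rec = EquationRecord(**raw)
        except Exception as exc:
            raise RegistrySchemaError(
                f"invalid equation record {raw.get('eq_id', '<unnamed>')!r}: {exc}"
            ) from exc
        if rec.eq_id in seen:
            raise RegistrySchemaError(f"duplicate eq_id: {rec.eq_id}")
        seen.add(rec.eq_id)
        records.append(rec)
    return records


def _packaged_registry_path():
    return resources.files("emeq.data").joinpath("registry.yaml")


def packaged_registry() -> list[EquationRecord]:
    """The packaged 32-equation registry (5 source publications)."""
    with resources.as_file(_packaged_registry_path()) as p:
        return load_registry(p)


def packaged_registry_meta() -> RegistryMeta:
    """Selection-cascade metadata shipped with the packaged registry."""
    with resources.as_file(_packaged_registry_path()) as p:
        with open(p, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    return RegistryMeta(**doc["meta"])


def apply_all(
    registry: Sequence[EquationRecord],
    diets: Sequence[CompletedDiet],
) -> PredictionSet:
    """Evaluate every equation on every completed diet.

    Returns a :class:`PredictionSet` with ``len(registry) * len(diets)``
    rows; the per-kg-DM response is the daily output divided by the diet's
    DMI (exact).
    """
    rows = []
    for eq in registry:
        for diet in diets:
            try:
                g_day = evaluate_daily(eq, diet)
            except EvaluationError:
                raise
            except Exception as exc:
                raise EvaluationError(
                    f"evaluating {eq.eq_id} on diet {diet.diet_id}: {exc}"
                ) from exc
            rows.append(
                {
                    "eq_id": eq.eq_id,
                    "diet_id": diet.diet_id,
                    "ch4_g_per_day": g_day,
                    "ch4_g_per_kg_dm": g_day / diet.dmi,
                    "dmi_kg_d": diet.dmi,
                    "me_mj_kg": diet.me_conc,
                    "ge_mj_kg": diet.ge_conc,
                    "ndf_pct": diet.ndf_pct,
                    "adf_pct": diet.adf_pct,
                    "cp_pct": diet.cp_pct,
                    "ee_pct": diet.ee_pct,
                    "fa_pct": diet.fa_pct,
                    "forage_pct": diet.forage_pct,
                    "ash_pct": diet.ash_pct,
                }
            )
    return PredictionSet(pd.DataFrame(rows, columns=list(PREDICTION_COLUMNS)))


@dataclass(frozen=True)
class ExtremesTable:
    """Per-diet minimum/maximum emissions plus the global envelope."""

    per_diet: pd.DataFrame  # columns diet_id, min, max
    global_min: float
    global_max: float
    spread: float


def diet_extremes(preds: PredictionSet | pd.DataFrame) -> ExtremesTable:
    """Per-diet min-max emissions envelope (g CH4/kg DM) over equations.

    Accepts a :class:`PredictionSet` or any frame with ``diet_id`` and
    ``ch4_g_per_kg_dm`` columns (so published per-diet summary values can be
    fed through directly).
    """
    frame = preds.frame if isinstance(preds, PredictionSet) else preds
    if frame.empty:
        raise ValueError("cannot compute extremes of an empty prediction set")
    grouped = frame.groupby("diet_id", sort=False)["ch4_g_per_kg_dm"]
    per_diet = grouped.agg(["min", "max"]).reset_index()
    gmin = float(per_diet["min"].min())
    gmax = float(per_diet["max"].max())
    return ExtremesTable(
        per_diet=per_diet,
        global_min=gmin,
        global_max=gmax,
        spread=gmax - gmin,
    )
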