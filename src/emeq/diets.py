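"""Dairy ration data model and ingestion.

A diet is described by its metabolisable energy intake (MEI, MJ/day) and its
nutrient composition as percentages of dry matter: crude protein (CP), fatty
acids (FA), ether extract (EE), neutral and acid detergent fibre (NDF, ADF)
and the forage proportion. The package ships a fixture set of 15 UK dairy
rations (13 lactating, 2 dry-cow) that spans typical commercial feeding
systems; :func:`packaged_diets` returns it.

Dry matter intake, energy concentrations and ash content are not part of a
:class:`DietProfile`; they are filled in by :mod:`emeq.synth` to produce a
:class:`CompletedDiet`, the input the prediction equations need.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

__all__ = [
    "Cohort",
    "DietProfile",
    "CompletedDiet",
    "DIET_CSV_COLUMNS",
    "load_diets",
    "save_diets",
    "packaged_diets",
    "diets_to_frame",
]

logger = logging.getLogger(__name__)

Cohort = Literal["lactating", "dry"]

#: Canonical diet CSV header (comma separated, decimal point, UTF-8).
DIET_CSV_COLUMNS = (
    "diet_id",
    "cohort",
    "mei_mj_d",
    "cp_pct",
    "fa_pct",
    "ee_pct",
    "ndf_pct",
    "adf_pct",
    "forage_pct",
)

_PCT_FIELDS = ("cp_pct", "fa_pct", "ee_pct", "ndf_pct", "adf_pct", "forage_pct")


class DietValidationError(ValueError):
    """A diet row violates a composition invariant."""


class DietSchemaError(ValueError):
    """A diet CSV is missing a required column."""


class DietProfile(BaseModel):
    """Nutrient composition of one ration.

    Percentages are stored as printed, i.e. g per 100 g DM (32.5 means
    32.5 % of DM), never as fractions.
    """

    model_config = ConfigDict(frozen=True)

    diet_id: str
    cohort: Cohort = "lactating"
    mei: float
    cp_pct: float
    fa_pct: float
    ee_pct: float
    ndf_pct: float
    adf_pct: float
    forage_pct: float

    @field_validator("mei")
    @classmethod
    def _mei_positive(cls, v: float) -> float:
        if not v > 0:
            raise ValueError(f"mei must be > 0, got {v}")
        return v

    @field_validator(*_PCT_FIELDS)
    @classmethod
    def _pct_in_range(cls, v: float) -> float:
        if not 0 <= v <= 100:
            raise ValueError(f"percentage outside [0, 100]: {v}")
        return v

    @model_validator(mode="after")
    def _adf_within_ndf(self) -> "DietProfile":
        # ADF is a subset of the NDF fibre fraction.
        if self.adf_pct > self.ndf_pct:
            raise ValueError(
                f"diet {self.diet_id}: adf_pct ({self.adf_pct}) exceeds "
                f"ndf_pct ({self.ndf_pct})"
            )
        return self


class CompletedDiet(DietProfile):
    """A diet with the intake-level variables required by the equations.

    ``me_conc`` (MJ/kg DM) must equal ``mei / dmi`` exactly, and gross energy
    cannot fall below metabolisable energy. ``completion_provenance`` records
    whether the values were measured or synthesised (strategy and seed).
    """

    dmi: float
    me_conc: float
    ge_conc: float
    ash_pct: float
    completion_provenance: str = "measured"

    @field_validator("dmi")
    @classmethod
    def _dmi_positive(cls, v: float) -> float:
        if not v > 0:
            raise ValueError(f"dmi must be > 0, got {v}")
        return v

    @model_validator(mode="after")
    def _energy_consistency(self) -> "CompletedDiet":
        if abs(self.me_conc * self.dmi - self.mei) / self.mei > 1e-9:
            raise ValueError(
                f"diet {self.diet_id}: me_conc * dmi != mei "
                f"({self.me_conc} * {self.dmi} vs {self.mei})"
            )
        if self.ge_conc < self.me_conc:
            raise ValueError(
                f"diet {self.diet_id}: ge_conc ({self.ge_conc}) below "
                f"me_conc ({self.me_conc})"
            )
        return self


def _profiles_from_frame(df: pd.DataFrame, source: str) -> list[DietProfile]:
    profiles = []
    for _, row in df.iterrows():
        try:
            profiles.append(
                DietProfile(
                    diet_id=str(row["diet_id"]),
                    cohort=str(row["cohort"]),
                    mei=float(row["mei_mj_d"]),
                    cp_pct=float(row["cp_pct"]),
                    fa_pct=float(row["fa_pct"]),
                    ee_pct=float(row["ee_pct"]),
                    ndf_pct=float(row["ndf_pct"]),
                    adf_pct=float(row["adf_pct"]),
                    forage_pct=float(row["forage_pct"]),
                )
            )
        except Exception as exc:  # pydantic wraps the field name in the message
            raise DietValidationError(
                f"{source}: invalid diet row {row['diet_id']!r}: {exc}"
            ) from exc
    return profiles


def load_diets(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> list[DietProfile]:
    """Read diets from a CSV file.

    Parameters
    ----------
    path
        CSV file with the :data:`DIET_CSV_COLUMNS` header.
    schema
        Optional mapping from the file's column names to the canonical ones,
        e.g. ``{"ration": "diet_id"}``.

    Returns
    -------
    list of :class:`DietProfile`, in file row order. An empty file yields an
    empty list with a logged warning.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns=dict(schema))
    if df.empty:
        logger.warning("diet file %s contains no rows", path)
        return []
    missing = [c for c in DIET_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise DietSchemaError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    return _profiles_from_frame(df, str(path))


def diets_to_frame(diets: Sequence[DietProfile]) -> pd.DataFrame:
    """Tabulate diets in the canonical CSV column order."""
    rows = []
    for d in diets:
        row = {
            "diet_id": d.diet_id,
            "cohort": d.cohort,
            "mei_mj_d": d.mei,
            "cp_pct": d.cp_pct,
            "fa_pct": d.fa_pct,
            "ee_pct": d.ee_pct,
            "ndf_pct": d.ndf_pct,
            "adf_pct": d.adf_pct,
            "forage_pct": d.forage_pct,
        }
        if isinstance(d, CompletedDiet):
            row.update(
                dmi_kg_d=d.dmi,
                me_mj_kg=d.me_conc,
                ge_mj_kg=d.ge_conc,
                ash_pct=d.ash_pct,
                provenance=d.completion_provenance,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def save_diets(diets: Sequence[DietProfile], path: str | Path) -> None:
    """Write diets to the canonical CSV dialect (round-trips with load)."""
    diets_to_frame(diets).to_csv(path, index=False)


def packaged_diets() -> list[DietProfile]:
    """The 15 packaged UK dairy diets (ids "1".."15"; 14-15 are dry-cow)."""
    with resources.as_file(
        resources.files("emeq.data").joinpath("diets_uk15.csv")
    ) as p:
        return load_diets(p)
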