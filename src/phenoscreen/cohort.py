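"""Shared containers: variable schemas, patient records, and the cohort table.

A cohort is a patient-by-variable table of *categorical* predictor values
(demographics, physical exam, clinical history, comorbidities) together with
the polysomnography outcome: the apnea-hypopnea index (AHI, events/hour), its
severity band, and the binary OSA status (AHI >= 5).  Missing predictor
entries are first-class citizens and are represented as NaN in memory and as
empty cells in the CSV dialect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# --------------------------------------------------------------------------
# AHI severity bands (closed integer intervals; severe is open-ended above)
# --------------------------------------------------------------------------

SEVERITIES = ("normal", "mild", "moderate", "severe")

#: lower edge of each severity band on the integer AHI scale
AHI_BAND_LOWER = {"normal": 0, "mild": 5, "moderate": 15, "severe": 30}
AHI_BAND_UPPER = {"normal": 4, "mild": 14, "moderate": 29, "severe": None}

OUTCOME_COLUMNS = ("ahi", "severity", "osa")
PHENOTYPES = ("low", "medium", "high")

VARIABLE_ROLES = ("demographic", "exam", "history", "comorbidity")


def severity_of_ahi(ahi: float) -> str:
    """Band an AHI value: 0-4 normal, 5-14 mild, 15-29 moderate, >=30 severe."""
    if ahi < 0:
        raise ValueError(f"AHI must be non-negative, got {ahi}")
    if ahi < 5:
        return "normal"
    if ahi < 15:
        return "mild"
    if ahi < 30:
        return "moderate"
    return "severe"


# --------------------------------------------------------------------------
# Variable schema
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class VariableSchema:
    """Description of one categorical predictor.

    Parameters
    ----------
    name : variable identifier, unique within a cohort.
    categories : ordered category labels (at least two).
    role : one of ``demographic | exam | history | comorbidity``.
    exclusion_flag : excluded from the cluster hierarchy even when
        univariately significant (e.g. witnessed apneas, which depend on
        third-party reporting).
    positive_category : the single category used as the "present" arm when a
        2x2 table is needed (crude odds ratios, AASM-style rules).  Defaults
        to the last category, which for yes/no variables is ``"yes"``.
    """

    name: str
    categories: tuple[str, ...]
    role: str = "history"
    exclusion_flag: bool = False
    positive_category: str | None = None

    def __post_init__(self) -> None:
        if len(self.categories) < 2:
            raise ValueError(f"{self.name}: need >= 2 categories")
        if len(set(self.categories)) != len(self.categories):
            raise ValueError(f"{self.name}: duplicate categories")
        if self.role not in VARIABLE_ROLES:
            raise ValueError(f"{self.name}: unknown role {self.role!r}")
        if self.positive_category is None:
            object.__setattr__(self, "positive_category", self.categories[-1])
        elif self.positive_category not in self.categories:
            raise ValueError(
                f"{self.name}: positive category {self.positive_category!r} "
                "not among categories"
            )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "categories": list(self.categories),
            "role": self.role,
            "exclusion_flag": self.exclusion_flag,
            "positive_category": self.positive_category,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "VariableSchema":
        return cls(
            name=d["name"],
            categories=tuple(d["categories"]),
            role=d.get("role", "history"),
            exclusion_flag=bool(d.get("exclusion_flag", False)),
            positive_category=d.get("positive_category"),
        )


def schema_to_json(schema: Mapping[str, VariableSchema]) -> str:
    return json.dumps([v.to_dict() for v in schema.values()], indent=2)


def schema_from_json(text: str) -> dict[str, VariableSchema]:
    return {d["name"]: VariableSchema.from_dict(d) for d in json.loads(text)}


# --------------------------------------------------------------------------
# Patient record and cohort
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PatientRecord:
    """One patient: categorical predictor values plus the PSG outcome."""

    id: str
    values: dict[str, str | None]
    ahi: int
    severity: str = field(default="")
    osa: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.ahi < 0:
            raise ValueError("negative AHI")
        sev = severity_of_ahi(self.ahi)
        if not self.severity:
            object.__setattr__(self, "severity", sev)
        elif self.severity != sev:
            raise ValueError(
                f"severity {self.severity!r} inconsistent with AHI {self.ahi}"
            )
        object.__setattr__(self, "osa", self.ahi >= 5)


class Cohort:
    """Patient-level table plus per-variable schema and missingness accounting.

    The underlying frame has one row per patient; predictor columns hold
    category strings or NaN, and the outcome columns are ``ahi`` (int),
    ``severity``, ``osa`` (0/1) and, for synthetic cohorts, the hidden
    ``true_phenotype``.  ``truth`` optionally retains the pre-masking
    predictor values so imputation can be scored against ground truth.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        schema: Mapping[str, VariableSchema],
        truth: pd.DataFrame | None = None,
        imputed_mask: pd.DataFrame | None = None,
    ) -> None:
        self.schema: dict[str, VariableSchema] = dict(schema)
        missing_cols = [c for c in OUTCOME_COLUMNS if c not in data.columns]
        if missing_cols:
            raise ValueError(f"cohort frame lacks outcome columns {missing_cols}")
        self.data = data.reset_index(drop=True)
        self.truth = None if truth is None else truth.reset_index(drop=True)
        self.imputed_mask = (
            None if imputed_mask is None else imputed_mask.reset_index(drop=True)
        )
        self.validate()

    # -- basic accessors ----------------------------------------------------

    @property
    def variables(self) -> list[str]:
        return [v for v in self.schema if v in self.data.columns]

    @property
    def n(self) -> int:
        return len(self.data)

    def predictor_frame(self) -> pd.DataFrame:
        return self.data[self.variables]

    def missing_fraction(self) -> pd.Series:
        """Per-variable proportion of missing entries."""
        return self.predictor_frame().isna().mean()

    def record(self, i: int) -> PatientRecord:
        row = self.data.iloc[i]
        values = {
            v: (None if pd.isna(row[v]) else str(row[v])) for v in self.variables
        }
        return PatientRecord(id=str(row.get("id", i)), values=values, ahi=int(row["ahi"]))

    def subset(self, mask) -> "Cohort":
        mask = np.asarray(mask)
        out = Cohort.__new__(Cohort)
        out.schema = dict(self.schema)
        out.data = self.data.loc[mask].reset_index(drop=True)
        out.truth = None if self.truth is None else self.truth.loc[mask].reset_index(drop=True)
        out.imputed_mask = (
            None
            if self.imputed_mask is None
            else self.imputed_mask.loc[mask].reset_index(drop=True)
        )
        return out

    def copy(self) -> "Cohort":
        return Cohort(
            self.data.copy(),
            self.schema,
            truth=None if self.truth is None else self.truth.copy(),
            imputed_mask=None if self.imputed_mask is None else self.imputed_mask.copy(),
        )

    def drop_variables(self, names: Iterable[str]) -> "Cohort":
        names = list(names)
        out = Cohort.__new__(Cohort)
        out.schema = {k: v for k, v in self.schema.items() if k not in names}
        out.data = self.data.drop(columns=[n for n in names if n in self.data.columns])
        out.truth = (
            None
            if self.truth is None
            else self.truth.drop(columns=[n for n in names if n in self.truth.columns])
        )
        out.imputed_mask = (
            None
            if self.imputed_mask is None
            else self.imputed_mask.drop(
                columns=[n for n in names if n in self.imputed_mask.columns]
            )
        )
        return out

    # -- consistency --------------------------------------------------------

    def validate(self) -> None:
        ahi = self.data["ahi"].to_numpy()
        if (ahi < 0).any():
            raise ValueError("negative AHI in cohort")
        expect_sev = np.array([severity_of_ahi(a) for a in ahi])
        if (self.data["severity"].to_numpy() != expect_sev).any():
            raise ValueError("severity column inconsistent with AHI")
        if (self.data["osa"].to_numpy().astype(int) != (ahi >= 5).astype(int)).any():
            raise ValueError("osa column inconsistent with AHI >= 5")
        for name in self.variables:
            col = self.data[name]
            observed = col.dropna()
            bad = set(observed) - set(self.schema[name].categories)
            if bad:
                raise ValueError(f"{name}: values outside category list: {bad}")

    # -- serialization ------------------------------------------------------

    def to_csv(self, path) -> None:
        """One row per patient, empty cell = missing."""
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, schema: Mapping[str, VariableSchema] | None = None) -> "Cohort":
        df = pd.read_csv(path, dtype=str, keep_default_na=True, na_values=[""])
        df["ahi"] = df["ahi"].astype(int)
        df["osa"] = df["osa"].astype(int)
        if schema is None:
            schema = {}
            for col in df.columns:
                if col in OUTCOME_COLUMNS or col in ("id", "true_phenotype"):
                    continue
                cats = tuple(sorted(df[col].dropna().unique()))
                while len(cats) < 2:  # degenerate/empty columns still need a schema
                    cats = cats + (f"__unobserved{len(cats)}__",)
                schema[col] = VariableSchema(name=col, categories=cats)
        else:
            schema = {k: v for k, v in schema.items() if k in df.columns}
        return cls(df, schema)
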