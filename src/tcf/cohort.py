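"""Cohort tables: the tabular data model shared by every pipeline stage.

A cohort is one row per ICU stay.  Columns are declared (not inferred) by a
schema file: continuous labs/vitals, Boolean history flags, an optional
identifier, and exactly one binary outcome column encoding all-cause death
within 28 days of ICU admission (1 = died).  Missing values are empty CSV
cells on disk and NaN in memory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

KINDS = ("continuous", "boolean")
ROLES = ("feature", "outcome", "identifier")


class SchemaError(ValueError):
    """Schema file and CSV disagree, or the schema itself is malformed."""


class CohortValidationError(ValueError):
    """Cohort values violate the data model (e.g. non-binary outcome)."""


@dataclass(frozen=True)
class ColumnSpec:
    """Declared metadata for one cohort column."""

    name: str
    kind: str = "continuous"
    units: str = ""
    role: str = "feature"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise SchemaError(f"unknown column kind {self.kind!r} for {self.name!r}")
        if self.role not in ROLES:
            raise SchemaError(f"unknown column role {self.role!r} for {self.name!r}")


@dataclass
class CohortTable:
    """A feature matrix plus outcome vector with per-column metadata.

    ``frame`` holds every declared column (features, outcome, identifiers) in
    schema order; missing entries are NaN.  The outcome column is binary and
    missing-free.
    """

    specs: list[ColumnSpec]
    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate column names in schema")
        if set(names) != set(self.frame.columns):
            missing = set(names) ^ set(self.frame.columns)
            raise SchemaError(f"schema/frame column mismatch: {sorted(missing)}")
        outcomes = [s for s in self.specs if s.role == "outcome"]
        if len(outcomes) != 1:
            raise SchemaError(f"expected exactly one outcome column, got {len(outcomes)}")
        if len(self.frame) < 1:
            raise CohortValidationError("cohort must contain at least one patient")
        y = self.frame[outcomes[0].name]
        if y.isna().any():
            raise CohortValidationError("outcome column contains missing values")
        if not y.isin((0, 1)).all():
            bad = sorted(set(y) - {0, 1})
            raise CohortValidationError(f"outcome values must be 0/1, found {bad}")
        for s in self.specs:
            if s.kind == "boolean" and s.role == "feature":
                col = self.frame[s.name].dropna()
                if not col.isin((0, 1)).all():
                    raise CohortValidationError(
                        f"boolean column {s.name!r} contains values outside {{0,1}}"
                    )

    # -- accessors -------------------------------------------------------

    @property
    def outcome_name(self) -> str:
        return next(s.name for s in self.specs if s.role == "outcome")

    @property
    def feature_specs(self) -> list[ColumnSpec]:
        return [s for s in self.specs if s.role == "feature"]

    @property
    def feature_names(self) -> list[str]:
        return [s.name for s in self.feature_specs]

    @property
    def X(self) -> pd.DataFrame:
        """Feature matrix (schema order), NaN for missing."""
        return self.frame[self.feature_names]

    @property
    def y(self) -> pd.Series:
        return self.frame[self.outcome_name].astype(int)

    @property
    def n_patients(self) -> int:
        return len(self.frame)

    @property
    def prevalence(self) -> float:
        return float(self.y.mean())

    def spec_for(self, name: str) -> ColumnSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    # -- derived tables --------------------------------------------------

    def with_frame(self, frame: pd.DataFrame) -> "CohortTable":
        """Same schema, new values (e.g. after imputation or scaling)."""
        return CohortTable(list(self.specs), frame)

    def select_features(self, names: Sequence[str]) -> "CohortTable":
        """Keep only the named features (plus outcome/identifier columns)."""
        keep = set(names)
        unknown = keep - set(self.feature_names)
        if unknown:
            raise KeyError(f"unknown features: {sorted(unknown)}")
        specs = [s for s in self.specs if s.role != "feature" or s.name in keep]
        return CohortTable(specs, self.frame[[s.name for s in specs]].copy())

    def drop_features(self, names: Iterable[str]) -> "CohortTable":
        drop = set(names)
        return self.select_features([n for n in self.feature_names if n not in drop])

    def subset_rows(self, index) -> "CohortTable":
        return CohortTable(list(self.specs), self.frame.loc[index].reset_index(drop=True))

    def append_feature(self, spec: ColumnSpec, values) -> "CohortTable":
        if spec.name in self.frame.columns:
            raise SchemaError(f"column {spec.name!r} already present")
        frame = self.frame.copy()
        frame[spec.name] = np.asarray(values, dtype=float)
        return CohortTable(list(self.specs) + [spec], frame)


# -- schema I/O ----------------------------------------------------------


def read_schema(path: str | Path) -> list[ColumnSpec]:
    """Load a YAML or JSON list of column declarations."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if isinstance(raw, dict) and "columns" in raw:
        raw = raw["columns"]
    if not isinstance(raw, list):
        raise SchemaError("schema must be a list of column entries")
    return [ColumnSpec(**entry) for entry in raw]


def write_schema(specs: Sequence[ColumnSpec], path: str | Path) -> None:
    entries = [
        {"name": s.name, "kind": s.kind, "units": s.units, "role": s.role} for s in specs
    ]
    Path(path).write_text(yaml.safe_dump(entries, sort_keys=False))


# -- cohort I/O ----------------------------------------------------------


def read_cohort(path: str | Path, schema: str | Path | Sequence[ColumnSpec]) -> CohortTable:
    """Read a header-row CSV against a declared schema.

    Empty cells become NaN.  Every CSV column must be declared and vice
    versa; outcome values must be binary and complete.
    """
    specs = list(schema) if not isinstance(schema, (str, Path)) else read_schema(schema)
    frame = pd.read_csv(path, dtype=float)
    declared = [s.name for s in specs]
    if set(frame.columns) != set(declared):
        extra = sorted(set(frame.columns) - set(declared))
        absent = sorted(set(declared) - set(frame.columns))
        raise SchemaError(f"CSV/schema mismatch: undeclared {extra}, missing {absent}")
    return CohortTable(specs, frame[declared])


def write_cohort(table: CohortTable, path: str | Path) -> None:
    """Write the cohort as RFC-4180 CSV; missing entries as empty cells."""
    table.frame.to_csv(path, index=False)
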