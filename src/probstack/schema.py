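"""Declarative column schemas and schema-checked delimited-text I/O.

A :class:`DatasetSchema` declares, for every column of a delimited text
file, a name, a semantic type and (optionally) an admissible range or
value set.  :func:`load_dataset` binds a CSV file to a schema and returns
a :class:`TabularDataset` — the container every downstream stage of the
toolkit operates on.  Two reference schemas for public heart-disease
datasets ship with the package (:func:`uci_schema`, :func:`chd_schema`).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SemanticType",
    "ColumnSpec",
    "DatasetSchema",
    "TabularDataset",
    "SchemaError",
    "LabelError",
    "load_dataset",
    "write_dataset",
    "uci_schema",
    "chd_schema",
    "schema_from_dict",
    "schema_to_dict",
    "load_schema_file",
    "MISSING_MARKERS",
]

#: Tokens treated as missing on ingestion (the historical UCI files use "?").
MISSING_MARKERS = ["", "NA", "?", "nan", "NaN"]

SEMANTIC_TYPES = frozenset(
    {"numeric_continuous", "numeric_ordinal", "binary", "categorical", "identifier"}
)


class SchemaError(ValueError):
    """Dataset does not match its declared schema."""


class LabelError(SchemaError):
    """Label column violates the binary-label contract."""


class SemanticType:
    """Namespace of the recognised semantic column types."""

    NUMERIC_CONTINUOUS = "numeric_continuous"
    NUMERIC_ORDINAL = "numeric_ordinal"
    BINARY = "binary"
    CATEGORICAL = "categorical"
    IDENTIFIER = "identifier"


@dataclass(frozen=True)
class ColumnSpec:
    """One column of a dataset: its name, semantic type and value domain.

    ``allowed_range`` is either a ``(min, max)`` pair for numeric columns
    or an explicit set of admissible values for ordinal/categorical ones.
    Binary columns always admit exactly ``{0, 1}``.
    """

    name: str
    semantic_type: str
    allowed_range: tuple | frozenset | None = None
    units: str | None = None

    def __post_init__(self) -> None:
        if self.semantic_type not in SEMANTIC_TYPES:
            raise SchemaError(
                f"unknown semantic_type {self.semantic_type!r} for column {self.name!r}"
            )
        rng = self.allowed_range
        if rng is not None:
            if isinstance(rng, (set, frozenset)):
                object.__setattr__(self, "allowed_range", frozenset(rng))
            else:
                lo, hi = rng
                if lo > hi:
                    raise SchemaError(
                        f"allowed_range min > max for column {self.name!r}"
                    )
                object.__setattr__(self, "allowed_range", (float(lo), float(hi)))
        if self.semantic_type == SemanticType.BINARY:
            object.__setattr__(self, "allowed_range", frozenset({0, 1}))

    @property
    def is_numeric(self) -> bool:
        return self.semantic_type in (
            SemanticType.NUMERIC_CONTINUOUS,
            SemanticType.NUMERIC_ORDINAL,
        )

    def values_in_range(self, values: pd.Series) -> pd.Series:
        """Boolean mask of non-missing values inside the declared domain."""
        obs = values.dropna()
        if self.allowed_range is None:
            return pd.Series(True, index=obs.index)
        if isinstance(self.allowed_range, frozenset):
            return obs.isin(self.allowed_range)
        lo, hi = self.allowed_range
        return (obs >= lo) & (obs <= hi)


@dataclass(frozen=True)
class DatasetSchema:
    """Ordered column specs plus the designated binary label column."""

    columns: tuple[ColumnSpec, ...]
    label_column: str
    positive_class: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "columns", tuple(self.columns))
        names = [c.name for c in self.columns]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate column names in schema")
        by_name = {c.name: c for c in self.columns}
        if self.label_column not in by_name:
            raise SchemaError(f"label column {self.label_column!r} not in schema")
        if by_name[self.label_column].semantic_type != SemanticType.BINARY:
            raise LabelError(f"label column {self.label_column!r} must be binary")

    def __getitem__(self, name: str) -> ColumnSpec:
        for c in self.columns:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def column_names(self) -> list[str]:
        return [c.name for c in self.columns]

    @property
    def feature_columns(self) -> list[str]:
        """Model-eligible columns: everything except identifiers and the label."""
        return [
            c.name
            for c in self.columns
            if c.name != self.label_column
            and c.semantic_type != SemanticType.IDENTIFIER
        ]

    @property
    def numeric_features(self) -> list[str]:
        return [
            c.name
            for c in self.columns
            if c.name != self.label_column and c.is_numeric
        ]

    def subset(self, feature_names: Sequence[str]) -> "DatasetSchema":
        """Schema restricted to ``feature_names`` (order kept) plus the label."""
        keep = set(feature_names) | {self.label_column}
        return DatasetSchema(
            columns=tuple(c for c in self.columns if c.name in keep),
            label_column=self.label_column,
            positive_class=self.positive_class,
        )


@dataclass
class TabularDataset:
    """A feature table bound to a schema, with a provenance log.

    ``values`` holds the feature columns (label excluded) in schema order;
    missing cells are ``NaN``.  ``labels`` is the 0/1 label vector.  Every
    mutation performed by the toolkit appends an ``(operation, parameters)``
    record to ``transform_log``.
    """

    schema: DatasetSchema
    values: pd.DataFrame
    labels: np.ndarray
    transform_log: list[tuple[str, dict]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.n_rows < 1:
            raise SchemaError("dataset must contain at least one row")
        if len(self.labels) != self.n_rows:
            raise LabelError("label vector length does not match row count")
        lab = self.labels[~pd.isna(self.labels)]
        if not np.isin(lab, [0, 1]).all():
            raise LabelError("labels must take values in {0, 1}")
        self.labels = self.labels.astype(int)
        expected = [c for c in self.schema.column_names if c != self.schema.label_column]
        if list(self.values.columns) != expected:
            missing = set(expected) - set(self.values.columns)
            raise SchemaError(f"value columns do not match schema (missing: {sorted(missing)})")

    @property
    def n_rows(self) -> int:
        return len(self.values)

    @property
    def feature_names(self) -> list[str]:
        return self.schema.feature_columns

    def feature_matrix(self) -> np.ndarray:
        """Model-eligible features as a float matrix (identifiers dropped)."""
        return self.values[self.feature_names].to_numpy(dtype=float)

    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def log(self, operation: str, **parameters) -> None:
        self.transform_log.append((operation, parameters))

    def copy(self) -> "TabularDataset":
        return TabularDataset(
            schema=self.schema,
            values=self.values.copy(),
            labels=self.labels.copy(),
            transform_log=list(self.transform_log),
        )

    def replace(
        self, values: pd.DataFrame | None = None, labels: np.ndarray | None = None
    ) -> "TabularDataset":
        return TabularDataset(
            schema=self.schema,
            values=self.values if values is None else values,
            labels=self.labels if labels is None else labels,
            transform_log=list(self.transform_log),
        )

    def select(self, feature_names: Sequence[str]) -> "TabularDataset":
        """Restrict to a feature subset, preserving schema order."""
        ordered = [c for c in self.values.columns if c in set(feature_names)]
        ds = TabularDataset(
            schema=self.schema.subset(ordered),
            values=self.values[ordered].copy(),
            labels=self.labels.copy(),
            transform_log=list(self.transform_log),
        )
        ds.log("select_features", features=ordered)
        return ds


def load_dataset(path: str | Path, schema: DatasetSchema) -> TabularDataset:
    """Read a headered CSV against ``schema``.

    Missing markers (``""``, ``"NA"``, ``"?"``, ``"nan"``) become NaN.
    Values outside a column's declared range are reported via
    ``warnings.warn`` but kept — declared ranges describe the reference
    sample, not hard constraints.

    Raises
    ------
    SchemaError
        If a schema column is absent from the file.
    LabelError
        If the label column contains anything but 0/1.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path, na_values=MISSING_MARKERS, keep_default_na=False, skipinitialspace=True
    )
    missing_cols = [c for c in schema.column_names if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"file {path.name} lacks schema columns: {missing_cols}")

    label_raw = df[schema.label_column]
    if label_raw.isna().any():
        raise LabelError("label column contains missing values")
    labels = pd.to_numeric(label_raw, errors="coerce")
    if labels.isna().any() or not labels.isin([0, 1]).all():
        raise LabelError(
            f"label column {schema.label_column!r} takes values outside {{0, 1}}"
        )

    feature_cols = [c for c in schema.column_names if c != schema.label_column]
    values = df[feature_cols].apply(pd.to_numeric, errors="coerce")

    for spec in schema.columns:
        if spec.name == schema.label_column or spec.allowed_range is None:
            continue
        in_range = spec.values_in_range(values[spec.name])
        n_out = int((~in_range).sum())
        if n_out:
            warnings.warn(
                f"column {spec.name!r}: {n_out} value(s) outside declared range "
                f"{spec.allowed_range}",
                stacklevel=2,
            )

    ds = TabularDataset(schema=schema, values=values, labels=labels.to_numpy())
    ds.log("load_dataset", path=str(path), n_rows=ds.n_rows, n_missing=ds.n_missing())
    return ds


def write_dataset(ds: TabularDataset, path: str | Path) -> Path:
    """Write the dataset back to CSV in schema column order."""
    path = Path(path)
    out = ds.values.copy()
    out[ds.schema.label_column] = ds.labels
    out = out[[c for c in ds.schema.column_names if c in out.columns]]
    out.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Reference schemas
# ---------------------------------------------------------------------------

def uci_schema() -> DatasetSchema:
    """14-column UCI heart-disease layout: 13 features plus ``target``.

    ``target`` = 1 means the patient has heart disease.
    """
    C = ColumnSpec
    T = SemanticType
    return DatasetSchema(
        columns=(
            C("age", T.NUMERIC_CONTINUOUS, (29, 77), units="years"),
            C("sex", T.BINARY),
            C("cp", T.NUMERIC_ORDINAL, frozenset({0, 1, 2, 3})),
            C("chol", T.NUMERIC_CONTINUOUS, (126, 564), units="mg/dL"),
            C("restbp", T.NUMERIC_CONTINUOUS, (94, 564), units="mm Hg"),
            C("fbs", T.BINARY),
            C("restecg", T.NUMERIC_ORDINAL, frozenset({0, 1, 2})),
            C("heartbeat", T.NUMERIC_CONTINUOUS, (71, 202), units="bpm"),
            C("exang", T.BINARY),
            C("oldpeak", T.NUMERIC_CONTINUOUS, (0, 6.2)),
            C("slope", T.NUMERIC_ORDINAL, frozenset({1, 2, 3})),
            C("ca", T.NUMERIC_ORDINAL, frozenset({0, 1, 2, 3})),
            C("thal", T.NUMERIC_ORDINAL, frozenset({0, 1, 2, 3})),
            C("target", T.BINARY),
        ),
        label_column="target",
        positive_class=1,
    )


def chd_schema() -> DatasetSchema:
    """13-column cardiovascular heart-disease layout (label ``death event``)."""
    C = ColumnSpec
    T = SemanticType
    return DatasetSchema(
        columns=(
            C("Age", T.NUMERIC_CONTINUOUS, (40, 95), units="years"),
            C("Sex", T.BINARY),
            C("Anemia", T.BINARY),
            C("High blood pressure", T.BINARY),
            C("Creatinine phosphokinase", T.NUMERIC_CONTINUOUS, (23, 7861), units="mcg/L"),
            C("Diabetes", T.BINARY),
            C("Ejection fraction", T.NUMERIC_CONTINUOUS, (14, 80), units="percent"),
            C("Platelets", T.NUMERIC_CONTINUOUS, (25.01, 850.0), units="kiloplatelets/mL"),
            C("Serum creatinine", T.NUMERIC_CONTINUOUS, (0.50, 9.40), units="mg/dL"),
            C("Serum sodium", T.NUMERIC_CONTINUOUS, (114, 148), units="mEq/L"),
            C("Smoking", T.BINARY),
            C("Time", T.NUMERIC_CONTINUOUS, (4, 285), units="days"),
            C("death event", T.BINARY),
        ),
        label_column="death event",
        positive_class=1,
    )


# ---------------------------------------------------------------------------
# Schema (de)serialization — YAML/JSON config dialect
# ---------------------------------------------------------------------------

def schema_to_dict(schema: DatasetSchema) -> dict:
    cols = []
    for c in schema.columns:
        d: dict = {"name": c.name, "semantic_type": c.semantic_type}
        if c.allowed_range is not None and c.semantic_type != SemanticType.BINARY:
            if isinstance(c.allowed_range, frozenset):
                d["allowed_range"] = sorted(c.allowed_range)
                d["range_kind"] = "values"
            else:
                d["allowed_range"] = list(c.allowed_range)
                d["range_kind"] = "interval"
        if c.units:
            d["units"] = c.units
        cols.append(d)
    return {
        "columns": cols,
        "label_column": schema.label_column,
        "positive_class": schema.positive_class,
    }


def schema_from_dict(d: dict) -> DatasetSchema:
    cols = []
    for cd in d["columns"]:
        rng = cd.get("allowed_range")
        if rng is not None:
            rng = frozenset(rng) if cd.get("range_kind") == "values" else tuple(rng)
        cols.append(
            ColumnSpec(
                name=cd["name"],
                semantic_type=cd["semantic_type"],
                allowed_range=rng,
                units=cd.get("units"),
            )
        )
    return DatasetSchema(
        columns=tuple(cols),
        label_column=d["label_column"],
        positive_class=d.get("positive_class", 1),
    )


_BUILTIN_SCHEMAS = {"uci": uci_schema, "chd": chd_schema}


def load_schema_file(path: str | Path) -> DatasetSchema:
    """Load a schema from a YAML or JSON config file, or by builtin name."""
    if str(path) in _BUILTIN_SCHEMAS:
        return _BUILTIN_SCHEMAS[str(path)]()
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return schema_from_dict(d)
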