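"""Typed mixed-type data container with delimited-text I/O.

Integrative clustering of tumour cohorts mixes real-valued measurements
(gene-signature scores, patient age), counts (copy-number events), ordered
grades and nominal/binary clinical annotations in one table.  ``MixedTable``
is the single entry point for such data: every column carries an explicit
declared kind, silent type inference is refused, and validation reports the
offending cell.  All simulated and real inputs flow through this container.

Feature kinds
-------------
continuous
    Real-valued; threshold splits.
integer
    Ordered counts (e.g. copy-number states); treated as ordered numeric.
ordinal
    Ordered categories with a declared level order (e.g. tumour grade).
nominal
    Unordered categories; level-subset splits.
binary
    Nominal with exactly two levels.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

KINDS = ("continuous", "integer", "ordinal", "nominal", "binary")
#: kinds whose values are category codes drawn from a declared level list
CATEGORICAL_KINDS = ("ordinal", "nominal", "binary")
#: kinds whose values are ordered (threshold splits in trees)
ORDERED_KINDS = ("continuous", "integer", "ordinal")
#: the single sentinel token encoding a missing cell on disk
MISSING_SENTINEL = "NA"


class SchemaError(ValueError):
    """A column is undeclared, mis-declared, or the schema itself is invalid."""


class ValidationError(ValueError):
    """A cell value violates its column's declared kind or level set."""


@dataclass(frozen=True)
class FeatureSchema:
    """Declaration of a single feature: name, kind and (if categorical) levels."""

    name: str
    kind: str
    levels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise SchemaError(
                f"feature {self.name!r}: unknown kind {self.kind!r}; must be one of {KINDS}"
            )
        if self.kind in CATEGORICAL_KINDS:
            if not self.levels:
                raise SchemaError(f"feature {self.name!r}: kind {self.kind!r} requires levels")
            levels = tuple(str(v) for v in self.levels)
            object.__setattr__(self, "levels", levels)
            if len(set(levels)) != len(levels):
                raise SchemaError(f"feature {self.name!r}: duplicate levels")
            if self.kind == "binary" and len(levels) != 2:
                raise SchemaError(f"feature {self.name!r}: binary requires exactly 2 levels")
        elif self.levels is not None:
            raise SchemaError(f"feature {self.name!r}: kind {self.kind!r} must not declare levels")

    @property
    def is_categorical(self) -> bool:
        return self.kind in CATEGORICAL_KINDS

    @property
    def is_ordered(self) -> bool:
        return self.kind in ORDERED_KINDS


class MixedTable:
    """A validated n x p mixed-type feature matrix with sample identifiers.

    Parameters
    ----------
    values : pandas.DataFrame
        One column per schema entry, in schema order.  Numeric kinds are
        stored as float64 (NaN = missing); categorical kinds as string
        values from the declared levels (None/NaN = missing).
    schema : sequence of FeatureSchema
    samples : sequence of str, optional
        Unique sample identifiers; defaults to ``S0001..``.
    labels : sequence, optional
        Ground-truth class labels (evaluation only, never used for fitting).
    """

    def __init__(
        self,
        values: pd.DataFrame,
        schema: Sequence[FeatureSchema],
        samples: Sequence[str] | None = None,
        labels: Sequence | None = None,
    ) -> None:
        self.schema = list(schema)
        names = [f.name for f in self.schema]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate feature names in schema")
        if list(values.columns) != names:
            missing = set(names) - set(values.columns)
            extra = set(values.columns) - set(names)
            raise SchemaError(
                f"columns do not match schema (missing={sorted(missing)}, undeclared={sorted(extra)})"
            )
        n = len(values)
        if samples is None:
            samples = [f"S{i + 1:04d}" for i in range(n)]
        self.samples = [str(s) for s in samples]
        if len(self.samples) != n:
            raise ValidationError("sample identifier count does not match row count")
        if len(set(self.samples)) != n:
            raise ValidationError("duplicate sample identifiers")
        self.values = self._coerce(values.reset_index(drop=True))
        self.labels = None if labels is None else np.asarray(labels)
        if self.labels is not None and len(self.labels) != n:
            raise ValidationError("label count does not match row count")
        self.validate()

    # -- construction helpers -------------------------------------------------

    def _coerce(self, df: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for f in self.schema:
            col = df[f.name]
            if f.is_categorical:
                col = col.astype(object).where(~pd.isna(col), None)
                col = col.map(lambda v: None if v is None else str(v))
            else:
                try:
                    col = pd.to_numeric(col, errors="raise").astype(float)
                except (ValueError, TypeError) as exc:
                    raise ValidationError(f"feature {f.name!r}: non-numeric value ({exc})") from exc
            out[f.name] = col
        return pd.DataFrame(out)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        schema: Sequence[FeatureSchema],
        samples: Sequence[str] | None = None,
        labels: Sequence | None = None,
    ) -> "MixedTable":
        return cls(df, schema, samples=samples, labels=labels)

    # -- basic properties -----------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def p(self) -> int:
        return len(self.schema)

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.schema]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.values.isna().to_numpy()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"MixedTable(n={self.n}, p={self.p})"

    # -- validation -----------------------------------------------------------

    def validate(self) -> None:
        """Raise ValidationError on the first invariant violation."""
        if self.n < 2:
            raise ValidationError("a MixedTable requires at least 2 samples")
        if self.p < 1:
            raise ValidationError("a MixedTable requires at least 1 feature")
        for j, f in enumerate(self.schema):
            if not f.is_categorical:
                continue
            col = self.values[f.name]
            levels = set(f.levels)
            for i, v in enumerate(col):
                if v is None or (isinstance(v, float) and np.isnan(v)):
                    continue
                if v not in levels:
                    raise ValidationError(
                        f"row {i} ({self.samples[i]!r}), column {f.name!r}: "
                        f"value {v!r} not in declared levels {f.levels}"
                    )

    def drop_incomplete(self) -> "MixedTable":
        """Return the complete-case subtable (rows with no missing cell)."""
        keep = ~self.missing_mask.any(axis=1)
        if keep.sum() < 2:
            raise ValidationError("fewer than 2 complete cases remain")
        labels = None if self.labels is None else self.labels[keep]
        return MixedTable(
            self.values.loc[keep].reset_index(drop=True),
            self.schema,
            samples=[s for s, k in zip(self.samples, keep) if k],
            labels=labels,
        )

    # -- numeric view for the forest engine -----------------------------------

    def to_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """Encode as (X, nominal_mask) for tree growing.

        Ordered kinds keep their numeric value (ordinal -> level rank);
        nominal/binary become level codes and are flagged in
        ``nominal_mask`` so trees use level-subset splits.  Missing cells
        become NaN; the forest engine rejects NaN (complete cases only).
        """
        X = np.empty((self.n, self.p), dtype=np.float64)
        nominal_mask = np.zeros(self.p, dtype=bool)
        for j, f in enumerate(self.schema):
            col = self.values[f.name]
            if f.kind in ("continuous", "integer"):
                X[:, j] = col.to_numpy(dtype=float)
            else:
                code = {lv: float(i) for i, lv in enumerate(f.levels)}
                X[:, j] = [np.nan if v is None else code[v] for v in col]
                if f.kind in ("nominal", "binary"):
                    nominal_mask[j] = True
        return X, nominal_mask

    def take(self, rows: Iterable[int]) -> "MixedTable":
        rows = list(rows)
        labels = None if self.labels is None else self.labels[rows]
        return MixedTable(
            self.values.iloc[rows].reset_index(drop=True),
            self.schema,
            samples=[self.samples[i] for i in rows],
            labels=labels,
        )


# -- schema sidecar I/O -------------------------------------------------------


def _schema_to_obj(table: MixedTable, id_column: str, label_column: str | None) -> dict:
    feats = []
    for f in table.schema:
        rec: dict = {"name": f.name, "kind": f.kind}
        if f.levels is not None:
            rec["levels"] = list(f.levels)
        feats.append(rec)
    obj: dict = {"id_column": id_column, "features": feats}
    if label_column is not None:
        obj["label_column"] = label_column
    return obj


def load_schema(schema_path: str) -> tuple[list[FeatureSchema], str | None, str | None]:
    """Read a YAML/JSON schema sidecar; returns (features, id_column, label_column)."""
    with open(schema_path) as fh:
        obj = yaml.safe_load(fh)
    if not isinstance(obj, dict) or "features" not in obj:
        raise SchemaError(f"{schema_path}: schema must be a mapping with a 'features' list")
    feats = []
    for rec in obj["features"]:
        if "kind" not in rec:
            raise SchemaError(f"{schema_path}: feature {rec.get('name')!r} declares no kind")
        feats.append(
            FeatureSchema(
                name=str(rec["name"]),
                kind=str(rec["kind"]),
                levels=tuple(str(v) for v in rec["levels"]) if rec.get("levels") else None,
            )
        )
    return feats, obj.get("id_column"), obj.get("label_column")


def _delimiter_for(path: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if os.path.splitext(path)[1].lower() in (".tsv", ".tab") else ","


def read_table(path: str, schema_path: str, delimiter: str | None = None) -> MixedTable:
    """Read a delimited text table plus its schema sidecar into a MixedTable.

    Every non-id, non-label column in the file must be declared in the
    schema; any undeclared column raises SchemaError.  Missing cells are
    encoded as ``NA``.
    """
    schema, id_column, label_column = load_schema(schema_path)
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(
        path, sep=sep, dtype=str, keep_default_na=False, na_values=[MISSING_SENTINEL]
    )
    declared = {f.name for f in schema}
    samples = None
    labels = None
    if id_column is not None:
        if id_column not in df.columns:
            raise SchemaError(f"id column {id_column!r} absent from {path}")
        samples = df[id_column].tolist()
    if label_column is not None and label_column in df.columns:
        labels = df[label_column].tolist()
    special = {id_column, label_column}
    for c in df.columns:
        if c not in declared and c not in special:
            raise SchemaError(f"column {c!r} in {path} is not declared in the schema")
    for f in schema:
        if f.name not in df.columns:
            raise SchemaError(f"declared feature {f.name!r} absent from {path}")
    return MixedTable(df[[f.name for f in schema]], schema, samples=samples, labels=labels)


def write_table(
    table: MixedTable,
    path: str,
    schema_path: str | None = None,
    delimiter: str | None = None,
    id_column: str = "sample",
    label_column: str = "class",
) -> str:
    """Write a MixedTable as delimited text plus a YAML schema sidecar.

    ``read_table(write_table(t))`` reproduces the data model exactly
    (floats are serialised with shortest round-trip repr).
    """
    sep = _delimiter_for(path, delimiter)
    out = pd.DataFrame({id_column: table.samples})
    if table.labels is not None:
        out[label_column] = table.labels
    for f in table.schema:
        col = table.values[f.name]
        if f.is_categorical:
            out[f.name] = [MISSING_SENTINEL if v is None else v for v in col]
        else:
            out[f.name] = [
                MISSING_SENTINEL if np.isnan(v) else repr(float(v)) for v in col.to_numpy()
            ]
    out.to_csv(path, sep=sep, index=False)
    if schema_path is None:
        schema_path = path + ".schema.yaml"
    obj = _schema_to_obj(table, id_column, label_column if table.labels is not None else None)
    with open(schema_path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
    return path
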