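"""Loading, validation and normalization of tabular obstetric records.

A :class:`DataDictionary` describes every column of a delivery-episode table
(type, units, admissible codes, null tokens).  :func:`load_table` reads a CSV
against it and produces a :class:`RecordTable` in which

* every configured missing token has been replaced by one canonical null
  sentinel (``NaN``),
* numeric cells are parsed to floats, and
* numeric cells that cannot be parsed are kept as their raw string and
  tagged *malformed* — they are conformance problems for the rule engine,
  never completeness problems, and must not crash the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

#: Null spellings recognized by default; configurable per column.
DEFAULT_MISSING_TOKENS: tuple[str, ...] = ("", "NA", "N/A", "NULL", "null", "-", "?")

#: Category used when a missing categorical value is imputed (distinct from
#: the raw-null sentinel: raw nulls are completeness, NULLIMP is modeling).
NULLIMP = "NULLIMP"

NUMERIC_KINDS = frozenset({"continuous", "count"})
COLUMN_KINDS = frozenset({"continuous", "count", "categorical", "date", "identifier"})


class SchemaError(ValueError):
    """Raised when a table's columns do not match the data dictionary."""


@dataclass(frozen=True)
class ColumnSpec:
    """Schema for one column of the record table."""

    name: str
    kind: str
    unit: str = ""
    value_set: tuple[str, ...] | None = None
    range: tuple[float, float] | None = None
    missing_tokens: tuple[str, ...] = DEFAULT_MISSING_TOKENS
    date_format: str | None = None
    fhir_code: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in COLUMN_KINDS:
            raise ValueError(f"unknown column kind {self.kind!r} for {self.name!r}")
        if self.range is not None and self.kind not in NUMERIC_KINDS:
            raise ValueError(f"range only allowed on numeric columns, not {self.name!r}")
        if self.value_set is not None and self.kind != "categorical":
            raise ValueError(f"value_set only allowed on categorical columns, not {self.name!r}")
        if not self.missing_tokens:
            raise ValueError(f"missing_tokens must be non-empty for {self.name!r}")

    @property
    def is_numeric(self) -> bool:
        return self.kind in NUMERIC_KINDS

    def to_dict(self) -> dict:
        out: dict = {"name": self.name, "kind": self.kind}
        if self.unit:
            out["unit"] = self.unit
        if self.value_set is not None:
            out["value_set"] = list(self.value_set)
        if self.range is not None:
            out["range"] = list(self.range)
        if tuple(self.missing_tokens) != DEFAULT_MISSING_TOKENS:
            out["missing_tokens"] = list(self.missing_tokens)
        if self.date_format:
            out["date_format"] = self.date_format
        if self.fhir_code:
            out["fhir_code"] = self.fhir_code
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ColumnSpec":
        return cls(
            name=d["name"],
            kind=d["kind"],
            unit=d.get("unit", ""),
            value_set=tuple(str(v) for v in d["value_set"]) if d.get("value_set") else None,
            range=tuple(float(v) for v in d["range"]) if d.get("range") else None,
            missing_tokens=tuple(d.get("missing_tokens", DEFAULT_MISSING_TOKENS)),
            date_format=d.get("date_format"),
            fhir_code=d.get("fhir_code"),
        )


@dataclass(frozen=True)
class DataDictionary:
    """Ordered collection of :class:`ColumnSpec` with unique names."""

    columns: tuple[ColumnSpec, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.columns]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate column names in dictionary: {dupes}")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.columns]

    def __getitem__(self, name: str) -> ColumnSpec:
        for c in self.columns:
            if c.name == name:
                return c
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(c.name == name for c in self.columns)

    def numeric_columns(self) -> list[str]:
        return [c.name for c in self.columns if c.is_numeric]

    def subset(self, names: list[str]) -> "DataDictionary":
        keep = [c for c in self.columns if c.name in set(names)]
        return DataDictionary(tuple(keep))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"columns": [c.to_dict() for c in self.columns]}, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "DataDictionary":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(tuple(ColumnSpec.from_dict(c) for c in cfg["columns"]))


@dataclass
class RecordTable:
    """Normalized record table: a DataFrame plus its dictionary.

    ``df`` holds canonical values: floats for numeric columns (NaN = null),
    strings for the rest (NaN = null).  ``malformed`` is a parallel boolean
    frame marking numeric cells whose raw text could not be parsed; such
    cells keep the raw string in ``df`` (hence an object dtype column).
    """

    dictionary: DataDictionary
    df: pd.DataFrame
    malformed: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        if list(self.df.columns) != self.dictionary.names:
            raise SchemaError(
                f"table columns {list(self.df.columns)} != dictionary {self.dictionary.names}"
            )

    def __len__(self) -> int:
        return len(self.df)

    def null_mask(self) -> pd.DataFrame:
        """True where a cell is canonically null (malformed cells are present)."""
        return self.df.isna() & ~self.malformed

    def numeric_values(self, column: str) -> pd.Series:
        """Float view of a numeric column; nulls *and* malformed cells are NaN."""
        if not self.dictionary[column].is_numeric:
            raise ValueError(f"{column!r} is not numeric")
        return pd.to_numeric(self.df[column], errors="coerce")

    def copy(self) -> "RecordTable":
        return RecordTable(self.dictionary, self.df.copy(), self.malformed.copy(), self.provenance)

    def row_record(self, i: int) -> dict:
        """One row as a plain mapping column -> value (NaN for nulls)."""
        return dict(zip(self.df.columns, self.df.iloc[i]))


def _parse_number(raw: str, decimal_comma: bool) -> float | None:
    s = raw.strip()
    if decimal_comma:
        s = s.replace(",", ".")
    try:
        v = float(s)
    except ValueError:
        return None
    return v if math.isfinite(v) else None


def normalize_table(
    df: pd.DataFrame,
    dictionary: DataDictionary,
    decimal_comma: bool = False,
    provenance: str = "",
) -> RecordTable:
    """Canonicalize a raw (string- or value-typed) frame against a dictionary.

    Missing tokens become NaN; numeric columns are parsed; unparseable
    numeric cells are retained as raw strings and flagged malformed.
    """
    got, want = list(df.columns), dictionary.names
    missing = [c for c in want if c not in got]
    extra = [c for c in got if c not in want]
    if missing or extra:
        raise SchemaError(f"schema mismatch: missing columns {missing}, extra columns {extra}")
    df = df[want]  # order-insensitive header

    out: dict[str, list] = {}
    bad: dict[str, list] = {}
    for spec in dictionary.columns:
        tokens = set(spec.missing_tokens)
        vals, flags = [], []
        for cell in df[spec.name]:
            if cell is None or (isinstance(cell, float) and math.isnan(cell)) or cell is pd.NA:
                vals.append(np.nan)
                flags.append(False)
                continue
            if isinstance(cell, str) and cell.strip() in tokens:
                vals.append(np.nan)
                flags.append(False)
                continue
            if spec.is_numeric:
                if isinstance(cell, (int, float, np.integer, np.floating)):
                    vals.append(float(cell))
                    flags.append(False)
                else:
                    num = _parse_number(str(cell), decimal_comma)
                    if num is None:
                        vals.append(str(cell))  # keep raw for conformance scoring
                        flags.append(True)
                    else:
                        vals.append(num)
                        flags.append(False)
            else:
                vals.append(str(cell))
                flags.append(False)
        out[spec.name] = vals
        bad[spec.name] = flags

    frame = pd.DataFrame(out, columns=want)
    # numeric columns without malformed cells get a float dtype
    for spec in dictionary.columns:
        if spec.is_numeric and not any(bad[spec.name]):
            frame[spec.name] = pd.to_numeric(frame[spec.name])
    mal = pd.DataFrame(bad, columns=want, dtype=bool)
    mal.index = frame.index
    return RecordTable(dictionary, frame, mal, provenance)


def load_table(
    path,
    dictionary: DataDictionary,
    decimal_comma: bool = False,
    provenance: str = "",
) -> RecordTable:
    """Read a CSV (RFC 4180, UTF-8, header row) and normalize it."""
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except OSError as exc:
        raise IOError(f"cannot read {path}: {exc}") from exc
    return normalize_table(raw, dictionary, decimal_comma, provenance or str(path))


def write_table(table: RecordTable, path) -> None:
    """Write a canonical table back to CSV; nulls serialize as empty cells."""
    out = table.df.copy()
    for spec in table.dictionary.columns:
        if spec.is_numeric:
            col = []
            for v, m in zip(out[spec.name], table.malformed[spec.name]):
                if m:
                    col.append(str(v))
                elif isinstance(v, float) and math.isnan(v):
                    col.append("")
                else:
                    f = float(v)
                    col.append(str(int(f)) if f.is_integer() else repr(f))
            out[spec.name] = col
        else:
            out[spec.name] = out[spec.name].fillna("")
    out.to_csv(path, index=False)


def column_missing_rates(table: RecordTable) -> dict[str, float]:
    """Fraction of canonically-null cells per column (malformed counts as present)."""
    if len(table) == 0:
        raise ValueError("cannot compute missing rates on an empty table")
    nulls = table.null_mask()
    return {c: float(nulls[c].mean()) for c in table.df.columns}


def schema_diff(df_columns: list[str], dictionary: DataDictionary) -> tuple[list[str], list[str]]:
    """(missing, extra) columns of a header relative to the dictionary."""
    want = set(dictionary.names)
    got = set(df_columns)
    return sorted(want - got), sorted(got - want)
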