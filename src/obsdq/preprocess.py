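"""Training-time preprocessing for the plausibility models.

Three fitted transforms, applied in order:

1. drop columns whose training missing rate is strictly above a threshold
   (default 0.80),
2. impute nulls — median for numeric columns, the reserved ``NULLIMP``
   category for everything else,
3. discretize numeric columns into at most 3 bins cut at the 1/3 and 2/3
   quantiles of the observed training values (linear-interpolation
   quantiles).

Bin intervals are right-closed: a value equal to a cut point falls in the
lower bin, values below the first edge in bin 1 and above the last edge in
the last bin, so the mapping is total on imputed tables.  Heavily tied
columns (counts with mode 0) may produce duplicate quantile edges; these
collapse to fewer bins rather than erroring.  Date and identifier columns
are passed through untouched — they are the rule engine's business, not the
Bayesian network's.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .records_io import (
    NULLIMP,
    DataDictionary,
    RecordTable,
    SchemaError,
    column_missing_rates,
)

BIN_LABELS = ("bin1", "bin2", "bin3")


@dataclass(frozen=True)
class ColumnBins:
    """Fitted discretization of one numeric column."""

    edges: tuple[float, ...]  # strictly increasing interior cut points (0..2)
    labels: tuple[str, ...]  # len(edges)+1 bin labels

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Map values to bin labels; right-closed intervals."""
        idx = np.searchsorted(np.asarray(self.edges), values, side="left")
        return np.asarray(self.labels, dtype=object)[idx]


@dataclass
class DiscretizationMap:
    per_column: dict[str, ColumnBins]
    fitted_rows: int


@dataclass
class PreprocessModel:
    """Everything needed to replay the training preprocessing on new rows."""

    dictionary: DataDictionary  # retained columns only
    dropped_columns: list[str]
    imputation_values: dict[str, object]  # median (float) or NULLIMP
    discretization: DiscretizationMap
    missing_rates_train: dict[str, float]
    missing_threshold: float

    def to_dict(self) -> dict:
        return {
            "version": 1,
            "dropped_columns": list(self.dropped_columns),
            "imputation_values": {
                k: (float(v) if isinstance(v, (int, float, np.floating)) else str(v))
                for k, v in self.imputation_values.items()
            },
            "discretization": {
                c: {"edges": list(b.edges), "labels": list(b.labels)}
                for c, b in self.discretization.per_column.items()
            },
            "fitted_rows": self.discretization.fitted_rows,
            "missing_rates_train": self.missing_rates_train,
            "missing_threshold": self.missing_threshold,
            "columns": [c.to_dict() for c in self.dictionary.columns],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessModel":
        from .records_io import ColumnSpec

        dictionary = DataDictionary(tuple(ColumnSpec.from_dict(c) for c in d["columns"]))
        imput = {}
        for k, v in d["imputation_values"].items():
            imput[k] = float(v) if dictionary[k].is_numeric else str(v)
        disc = DiscretizationMap(
            {
                c: ColumnBins(tuple(b["edges"]), tuple(b["labels"]))
                for c, b in d["discretization"].items()
            },
            d["fitted_rows"],
        )
        return cls(
            dictionary=dictionary,
            dropped_columns=list(d["dropped_columns"]),
            imputation_values=imput,
            discretization=disc,
            missing_rates_train=dict(d["missing_rates_train"]),
            missing_threshold=float(d["missing_threshold"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "PreprocessModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def quantile_edges(values: np.ndarray, n_bins: int = 3) -> tuple[float, ...]:
    """Interior cut points at the k/n_bins quantiles, duplicates collapsed."""
    qs = [k / n_bins for k in range(1, n_bins)]
    raw = np.quantile(values, qs, method="linear")
    edges: list[float] = []
    for e in raw:
        if not edges or e > edges[-1]:
            edges.append(float(e))
    return tuple(edges)


def fit_preprocess(train: RecordTable, missing_threshold: float = 0.8) -> PreprocessModel:
    """Fit drop/impute/discretize transforms on a training table."""
    if len(train) == 0:
        raise ValueError("cannot fit preprocessing on an empty table")
    rates = column_missing_rates(train)
    dropped = [c for c in train.dictionary.names if rates[c] > missing_threshold]
    retained = [c for c in train.dictionary.names if c not in dropped]
    if not retained:
        raise ValueError("all columns exceed the missing-rate threshold; nothing retained")

    sub_dict = train.dictionary.subset(retained)
    imputation: dict[str, object] = {}
    bins: dict[str, ColumnBins] = {}
    for spec in sub_dict.columns:
        if spec.is_numeric:
            obs = train.numeric_values(spec.name).dropna().to_numpy()
            if obs.size == 0:
                raise ValueError(f"numeric column {spec.name!r} has no observed values")
            imputation[spec.name] = float(np.median(obs))
            edges = quantile_edges(obs, 3)
            bins[spec.name] = ColumnBins(edges, BIN_LABELS[: len(edges) + 1])
        else:
            imputation[spec.name] = NULLIMP
    return PreprocessModel(
        dictionary=sub_dict,
        dropped_columns=dropped,
        imputation_values=imputation,
        discretization=DiscretizationMap(bins, len(train)),
        missing_rates_train=rates,
        missing_threshold=missing_threshold,
    )


def apply_preprocess(
    model: PreprocessModel, table: RecordTable
) -> tuple[RecordTable, pd.DataFrame]:
    """Drop columns and impute nulls; returns the new table and an imputed mask.

    Malformed numeric cells are also replaced by the training median and
    marked imputed — downstream numeric models must never see raw strings;
    the malformedness itself is a conformance finding for the rule engine.
    The input table is left untouched.
    """
    for c in model.dictionary.names:
        if c not in table.dictionary:
            raise SchemaError(f"table lacks retained column {c!r}")

    keep = model.dictionary.names
    df = table.df[keep].copy()
    mal = table.malformed[keep]
    imputed = pd.DataFrame(False, index=df.index, columns=keep)
    for spec in model.dictionary.columns:
        fill = model.imputation_values[spec.name]
        if spec.is_numeric:
            parsed = pd.to_numeric(df[spec.name], errors="coerce")
            need = parsed.isna()  # nulls and malformed alike
            parsed[need] = float(fill)
            df[spec.name] = parsed
            imputed[spec.name] = need.to_numpy() | mal[spec.name].to_numpy()
        else:
            need = df[spec.name].isna()
            df[spec.name] = df[spec.name].where(~need, str(fill))
            imputed[spec.name] = need.to_numpy()
    out = RecordTable(
        model.dictionary,
        df,
        pd.DataFrame(False, index=df.index, columns=keep),
        table.provenance,
    )
    return out, imputed


def discretize(model: PreprocessModel, table: RecordTable) -> RecordTable:
    """Replace numeric cells by bin labels; categorical columns pass through.

    Expects an imputed table (no nulls in numeric columns).
    """
    df = table.df.copy()
    for col, cb in model.discretization.per_column.items():
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="raise").to_numpy(dtype=float)
        df[col] = cb.assign(vals)
    out_dict = table.dictionary
    return RecordTable(
        out_dict,
        df,
        pd.DataFrame(False, index=df.index, columns=df.columns),
        table.provenance,
    )
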