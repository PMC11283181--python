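"""Completeness dimension: scored from training-set missingness.

Each column's completeness is one minus its training missing rate.  At the
record level the default aggregation weights each originally-null cell by
how complete that column usually is, so omitting a habitually well-filled
column (maternal age) costs more than omitting one that is sparse for
structural reasons (vacuum-delivery count).  An unweighted variant is kept
behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .records_io import RecordTable, column_missing_rates


@dataclass
class CompletenessModel:
    column_completeness: dict[str, float]  # 1 - training missing rate

    def to_dict(self) -> dict:
        return {"column_completeness": self.column_completeness}

    @classmethod
    def from_dict(cls, d: dict) -> "CompletenessModel":
        return cls({k: float(v) for k, v in d["column_completeness"].items()})


def fit_completeness(train: RecordTable) -> CompletenessModel:
    rates = column_missing_rates(train)  # raises on empty table
    return CompletenessModel({c: 1.0 - r for c, r in rates.items()})


def record_completeness(
    model: CompletenessModel,
    null_mask: Mapping[str, bool],
    weighted: bool = True,
) -> float:
    """Score in [0,1]: 1 = fully observed, 0 = fully null.

    ``null_mask`` marks the record's originally-null cells (before any
    imputation).  Weighted mode: score = 1 - sum(w_j over null j) / sum(w_j),
    with w_j the column's training completeness.  Columns the model has never
    seen are ignored.
    """
    cols = [c for c in model.column_completeness if c in null_mask]
    if not cols:
        return 1.0
    if weighted:
        weights = {c: model.column_completeness[c] for c in cols}
        total = sum(weights.values())
        if total <= 0.0:
            # every column was fully null in training; fall back to counting
            weights = {c: 1.0 for c in cols}
            total = float(len(cols))
        lost = sum(weights[c] for c in cols if null_mask[c])
        return 1.0 - lost / total
    n_null = sum(1 for c in cols if null_mask[c])
    return 1.0 - n_null / len(cols)
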