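"""Fusion of the dimension sub-scores into one per-record quality score.

Every detector's native output is first converted to a sub-score in [0,1]
with 1 = best quality:

==================  =========================================================
completeness        training-completeness-weighted non-missingness
bn                  mean normalized posterior score over scored cells
context_tree        1 - flagged cells / evaluated cells
iqr                 1 - flagged cells / evaluated numeric cells
envelope, lof       1 if the row is not flagged, else 0
rules_conformance   pass ratio of applicable conformance rules
rules_plausibility  pass ratio of applicable plausibility rules
==================  =========================================================

The fused score is the weighted arithmetic mean.  Default weights put the
rule system heaviest and the missingness and IQR components lightest, and
are fully overridable in configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

COMPONENTS = (
    "rules_conformance",
    "rules_plausibility",
    "bn",
    "context_tree",
    "envelope",
    "lof",
    "iqr",
    "completeness",
)

DEFAULT_WEIGHTS = {
    "rules_conformance": 0.20,
    "rules_plausibility": 0.20,
    "bn": 0.25,
    "context_tree": 0.15,
    "envelope": 0.05,
    "lof": 0.05,
    "iqr": 0.05,
    "completeness": 0.05,
}


class WeightError(ValueError):
    """Invalid score-weight configuration."""


@dataclass(frozen=True)
class ScoreWeights:
    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))

    def __post_init__(self) -> None:
        unknown = set(self.weights) - set(COMPONENTS)
        if unknown:
            raise WeightError(f"unknown components {sorted(unknown)}")
        missing = set(COMPONENTS) - set(self.weights)
        if missing:
            raise WeightError(f"missing components {sorted(missing)}")
        w = self.weights
        if any(v < 0 for v in w.values()):
            raise WeightError("weights must be nonnegative")
        if abs(sum(w.values()) - 1.0) > 1e-9:
            raise WeightError(f"weights must sum to 1, got {sum(w.values())!r}")
        if w["rules_conformance"] + w["rules_plausibility"] <= max(w["completeness"], w["iqr"]):
            raise WeightError(
                "rule weights must dominate: w_rules_conformance + w_rules_plausibility "
                "> max(w_completeness, w_iqr)"
            )

    def digest(self) -> str:
        import hashlib

        payload = json.dumps({k: self.weights[k] for k in sorted(self.weights)})
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_dict(self) -> dict:
        return dict(self.weights)

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreWeights":
        return cls({k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class CellFinding:
    """One flag raised by one detector, with a human-readable justification."""

    detector: str
    column: str
    message: str
    score: float | None = None  # detector-native score/probability if any

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RecordQualityReport:
    record_id: str
    subscores: dict[str, float]
    score: float
    findings: list[CellFinding]
    model_version: str
    timestamp: str

    def to_dict(self) -> dict:
        return {
            "record_id": self.record_id,
            "subscores": self.subscores,
            "score": self.score,
            "findings": [f.to_dict() for f in self.findings],
            "model_version": self.model_version,
            "timestamp": self.timestamp,
        }


def fuse(subscores: dict[str, float], weights: ScoreWeights) -> float:
    """Weighted arithmetic mean of the component sub-scores."""
    missing = set(COMPONENTS) - set(subscores)
    if missing:
        raise KeyError(f"missing sub-scores for {sorted(missing)}")
    for k, v in subscores.items():
        if not 0.0 <= v <= 1.0 + 1e-12:
            raise ValueError(f"sub-score {k}={v} outside [0,1]")
    return float(sum(weights.weights[k] * subscores[k] for k in COMPONENTS))


def batch_summary(scores: list[float]) -> dict:
    """Mean and IQR of a scored batch (the tool's batch-level report)."""
    if not scores:
        return {"n": 0, "mean": None, "iqr": None}
    arr = np.asarray(scores, dtype=float)
    q1, q3 = np.quantile(arr, [0.25, 0.75])
    return {"n": int(arr.size), "mean": float(arr.mean()), "iqr": float(q3 - q1)}
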