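"""Declarative expert rules for conformance and domain plausibility.

A rule is a small declarative predicate over a single record: value-set
membership, numeric range, date format, a cross-column comparison, or
monotonicity of a measurement series.  The engine is the reproducible part;
the shipped obstetrics rulebook (17 rules, ``data/default_rules.yaml``) is
plain configuration and can be replaced wholesale.

Evaluation semantics:

* a rule whose referenced cells are all null is ``not_applicable`` — record
  incompleteness is the completeness dimension's business, and must not be
  double-penalized here;
* cross-column and series rules need every operand observed, otherwise
  ``not_applicable``;
* for numeric-range rules, a *malformed* cell (raw text that failed numeric
  parsing) is evaluable and fails: a non-number violates every numeric
  range, which is exactly the type-conformance check the rulebook needs;
* rules referencing columns absent from the record are skipped with a
  warning, never an error.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass
from importlib import resources

import yaml

RULE_KINDS = frozenset(
    {"value_set", "numeric_range", "date_format", "cross_column_comparison", "monotone_series"}
)
DIMENSIONS = frozenset({"conformance", "plausibility"})

_OPS = {
    "le": lambda a, b: a <= b,
    "lt": lambda a, b: a < b,
    "ge": lambda a, b: a >= b,
    "gt": lambda a, b: a > b,
    "eq": lambda a, b: a == b,
}
_OP_TEXT = {"le": "<=", "lt": "<", "ge": ">=", "gt": ">", "eq": "=="}


class RuleConfigError(ValueError):
    """Malformed rule configuration."""


@dataclass(frozen=True)
class Rule:
    id: str
    dimension: str
    description: str
    kind: str
    params: dict

    def __post_init__(self) -> None:
        if self.kind not in RULE_KINDS:
            raise RuleConfigError(f"rule {self.id!r}: unknown predicate kind {self.kind!r}")
        if self.dimension not in DIMENSIONS:
            raise RuleConfigError(f"rule {self.id!r}: unknown dimension {self.dimension!r}")

    def referenced_columns(self) -> list[str]:
        p = self.params
        if self.kind in ("value_set", "numeric_range", "monotone_series"):
            return list(p["columns"])
        if self.kind == "date_format":
            return [p["column"]]
        return [p["left"], p["right"]]


@dataclass(frozen=True)
class RuleResult:
    rule_id: str
    dimension: str
    status: str  # pass | fail | not_applicable
    message: str


def _is_null(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def _as_number(v) -> float | None:
    """None for nulls AND for malformed (non-parsable) cells."""
    if _is_null(v):
        return None
    if isinstance(v, (int, float)):
        return float(v)
    try:
        return float(str(v).strip())
    except ValueError:
        return None


def load_rules(config) -> list[Rule]:
    """Load rules from a YAML path, an open mapping, or a list of dicts."""
    if isinstance(config, (str, bytes)) or hasattr(config, "__fspath__"):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if isinstance(config, dict):
        entries = config.get("rules", [])
    else:
        entries = config or []
    rules = []
    for e in entries:
        try:
            rid = e["id"]
            rules.append(
                Rule(
                    id=rid,
                    dimension=e["dimension"],
                    description=e.get("description", ""),
                    kind=e["kind"],
                    params={
                        k: v for k, v in e.items()
                        if k not in ("id", "dimension", "description", "kind")
                    },
                )
            )
        except KeyError as exc:
            raise RuleConfigError(f"rule entry {e.get('id', '?')!r} missing field {exc}") from exc
    return rules


def default_rules() -> list[Rule]:
    """The shipped 17-rule obstetrics rulebook."""
    ref = resources.files("obsdq").joinpath("data/default_rules.yaml")
    with ref.open() as fh:
        return load_rules(yaml.safe_load(fh))


def _date_regex(fmt: str) -> re.Pattern:
    # d/m/Y with 1- or 2-digit day and month, 4-digit year
    if fmt in ("d/m/Y", "%d/%m/%Y"):
        return re.compile(r"^\d{1,2}/\d{1,2}/\d{4}$")
    raise RuleConfigError(f"unsupported date format {fmt!r}")


def _eval_rule(rule: Rule, record: dict) -> RuleResult:
    p = rule.params
    kind = rule.kind

    if kind == "value_set":
        allowed = {str(v) for v in p["values"]}
        offenders = []
        evaluable = 0
        for col in p["columns"]:
            v = record[col]
            if _is_null(v):
                continue
            evaluable += 1
            sv = str(v)
            if sv not in allowed:
                # a numeric cell like 11.0 should compare as "11"
                num = _as_number(v)
                if num is not None and num.is_integer() and str(int(num)) in allowed:
                    continue
                offenders.append(f"{col}={sv}")
        if evaluable == 0:
            return RuleResult(rule.id, rule.dimension, "not_applicable",
                              f"{rule.id}: no evaluable cells")
        if offenders:
            return RuleResult(rule.id, rule.dimension, "fail",
                              f"{rule.id}: value(s) outside admissible set: {', '.join(offenders)}")
        return RuleResult(rule.id, rule.dimension, "pass", f"{rule.id}: ok")

    if kind == "numeric_range":
        lo = p.get("min")
        hi = p.get("max")
        integer = bool(p.get("integer", False))
        offenders = []
        evaluable = 0
        for col in p["columns"]:
            v = record[col]
            if _is_null(v):
                continue
            evaluable += 1
            num = _as_number(v)
            if num is None:
                offenders.append(f"{col}={v!r} (not a number)")
                continue
            if integer and not float(num).is_integer():
                offenders.append(f"{col}={num:g} (not an integer)")
                continue
            if (lo is not None and num < lo) or (hi is not None and num > hi):
                offenders.append(f"{col}={num:g} outside [{lo}, {hi}]")
        if evaluable == 0:
            return RuleResult(rule.id, rule.dimension, "not_applicable",
                              f"{rule.id}: no evaluable cells")
        if offenders:
            return RuleResult(rule.id, rule.dimension, "fail",
                              f"{rule.id}: {'; '.join(offenders)}")
        return RuleResult(rule.id, rule.dimension, "pass", f"{rule.id}: ok")

    if kind == "date_format":
        col = p["column"]
        v = record[col]
        if _is_null(v):
            return RuleResult(rule.id, rule.dimension, "not_applicable", f"{rule.id}: {col} null")
        pattern = _date_regex(p.get("format", "d/m/Y"))
        sv = str(v)
        if pattern.match(sv):
            day, month, year = (int(x) for x in sv.split("/"))
            if 1 <= day <= 31 and 1 <= month <= 12 and 1000 <= year <= 9999:
                return RuleResult(rule.id, rule.dimension, "pass", f"{rule.id}: ok")
        return RuleResult(rule.id, rule.dimension, "fail",
                          f"{rule.id}: {col}={sv!r} not in d/m/Y format")

    if kind == "cross_column_comparison":
        left, right, op = p["left"], p["right"], p.get("op", "le")
        a, b = _as_number(record[left]), _as_number(record[right])
        if a is None or b is None:
            return RuleResult(rule.id, rule.dimension, "not_applicable",
                              f"{rule.id}: operand missing")
        if _OPS[op](a, b):
            return RuleResult(rule.id, rule.dimension, "pass", f"{rule.id}: ok")
        return RuleResult(
            rule.id, rule.dimension, "fail",
            f"{rule.id}: expected {left} {_OP_TEXT[op]} {right}, got {a:g} vs {b:g}",
        )

    # monotone_series: strictly increasing across entries separated by more
    # than min_separation on the spacing axis (e.g. ultrasound weeks)
    cols = list(p["columns"])
    spacing = list(p.get("spacing", range(len(cols))))
    min_sep = float(p.get("min_separation", 0))
    offenders = []
    checked = 0
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if spacing[j] - spacing[i] <= min_sep:
                continue
            a, b = _as_number(record[cols[i]]), _as_number(record[cols[j]])
            if a is None or b is None:
                continue
            checked += 1
            if not b > a:
                offenders.append(f"{cols[j]}={b:g} not > {cols[i]}={a:g}")
    if checked == 0:
        return RuleResult(rule.id, rule.dimension, "not_applicable",
                          f"{rule.id}: no evaluable pair")
    if offenders:
        return RuleResult(rule.id, rule.dimension, "fail", f"{rule.id}: {'; '.join(offenders)}")
    return RuleResult(rule.id, rule.dimension, "pass", f"{rule.id}: ok")


def evaluate_rules(rules: list[Rule], record: dict) -> list[RuleResult]:
    """Evaluate every rule on one normalized record (a column -> value map).

    Rules referencing columns the record lacks are skipped with a warning.
    Pure: repeated evaluation of the same inputs is identical.
    """
    results = []
    for rule in rules:
        missing = [c for c in rule.referenced_columns() if c not in record]
        if missing:
            warnings.warn(f"rule {rule.id} skipped: record lacks columns {missing}")
            continue
        results.append(_eval_rule(rule, record))
    return results


def rule_subscores(results: list[RuleResult]) -> dict[str, float]:
    """Per-dimension pass ratio; a dimension with zero applicable rules is 1.0."""
    out = {}
    for dim, key in (("conformance", "conformance"), ("plausibility", "rule_plausibility")):
        applicable = [r for r in results if r.dimension == dim and r.status != "not_applicable"]
        if not applicable:
            out[key] = 1.0
        else:
            out[key] = sum(1 for r in applicable if r.status == "pass") / len(applicable)
    return out
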