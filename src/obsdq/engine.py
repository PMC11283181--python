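"""End-to-end quality engine: fit every model on a training table, score new
records, and persist/reload the whole model directory as structured text."""

from __future__ import annotations

import json
import math
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bn as bnmod
from . import outliers as out
from .completeness import CompletenessModel, fit_completeness, record_completeness
from .preprocess import PreprocessModel, apply_preprocess, discretize, fit_preprocess
from .records_io import DataDictionary, RecordTable
from .rules import Rule, RuleResult, default_rules, evaluate_rules, load_rules, rule_subscores
from .scoring import (
    COMPONENTS,
    CellFinding,
    RecordQualityReport,
    ScoreWeights,
    batch_summary,
    fuse,
)

MODEL_VERSION = "obsdq-0.1.0"

#: columns with more than this many distinct states stay out of the BN and
#: the context trees (CPT size explodes; identifiers carry no structure)
MAX_BN_STATES = 30


@dataclass
class QualityEngine:
    dictionary: DataDictionary
    preprocess: PreprocessModel
    completeness: CompletenessModel
    net: bnmod.DiscreteBayesNet
    bn_columns: list[str]
    iqr: out.IQRBounds
    envelope: out.EnvelopeModel
    lof: out.LOFModel
    trees: dict[str, out.ContextTree]
    rules: list[Rule]
    weights: ScoreWeights
    seed: int
    trained_at: str
    numeric_columns: list[str] = field(default_factory=list)

    # ------------------------------------------------------------------ fit
    @classmethod
    def fit(
        cls,
        train: RecordTable,
        weights: ScoreWeights | None = None,
        rules: list[Rule] | None = None,
        seed: int = 0,
        max_parents: int = 3,
        restarts: int = 3,
        lof_k: int = 20,
        lof_threshold: float = 1.5,
        envelope_confidence: float = 0.99,
        tree_max_depth: int = 4,
        tree_min_branch: int = 50,
        tree_conf: float = 0.99,
        tree_gap_mult: float = 1.5,
        missing_threshold: float = 0.8,
        alpha: float = 1.0,
    ) -> "QualityEngine":
        weights = weights or ScoreWeights()
        rules = default_rules() if rules is None else rules

        completeness = fit_completeness(train)
        pre = fit_preprocess(train, missing_threshold)
        imputed, _ = apply_preprocess(pre, train)
        disc = discretize(pre, imputed)

        bn_cols = []
        for spec in pre.dictionary.columns:
            if spec.kind in ("identifier", "date"):
                continue
            if disc.df[spec.name].astype(str).nunique() > MAX_BN_STATES:
                continue
            bn_cols.append(spec.name)
        structure = bnmod.learn_structure(
            disc.df[bn_cols], max_parents=max_parents, seed=seed, restarts=restarts
        )
        net = bnmod.fit_cpts(structure, disc.df[bn_cols], alpha=alpha)

        num_cols = [c for c in pre.dictionary.numeric_columns()]
        iqr = out.fit_iqr(train, [c for c in num_cols])
        matrix = imputed.df[num_cols].to_numpy(dtype=float)
        envelope = out.fit_envelope(matrix, num_cols, confidence=envelope_confidence)
        lof = out.fit_lof(matrix, num_cols, k=lof_k, threshold=lof_threshold)

        trees = {}
        for target in bn_cols:
            trees[target] = out.fit_context_tree(
                imputed,
                target,
                predictors=[c for c in bn_cols if c != target],
                max_depth=tree_max_depth,
                min_branch=tree_min_branch,
                conf=tree_conf,
                gap_mult=tree_gap_mult,
            )

        return cls(
            dictionary=train.dictionary,
            preprocess=pre,
            completeness=completeness,
            net=net,
            bn_columns=bn_cols,
            iqr=iqr,
            envelope=envelope,
            lof=lof,
            trees=trees,
            rules=rules,
            weights=weights,
            seed=seed,
            trained_at=time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
            numeric_columns=num_cols,
        )

    # ---------------------------------------------------------------- score
    def score_table(
        self, table: RecordTable
    ) -> tuple[list[RecordQualityReport], dict]:
        """One report per row plus a batch summary; never aborts on a bad row."""
        imputed, imp_mask = apply_preprocess(self.preprocess, table)
        disc = discretize(self.preprocess, imputed)
        null_mask = table.null_mask()
        num_frame = pd.DataFrame(
            {
                c: table.numeric_values(c)
                for c in self.preprocess.dictionary.numeric_columns()
                if c in table.df.columns
            }
        )
        id_col = next(
            (c.name for c in self.dictionary.columns if c.kind == "identifier"), None
        )

        reports: list[RecordQualityReport] = []
        for i in range(len(table)):
            rid = str(table.df[id_col].iloc[i]) if id_col else str(i)
            try:
                reports.append(
                    self._score_row(table, imputed, disc, imp_mask, null_mask, num_frame, i, rid)
                )
            except Exception as exc:  # collected, batch never aborts on one row
                reports.append(
                    RecordQualityReport(
                        record_id=rid,
                        subscores={},
                        score=float("nan"),
                        findings=[CellFinding("error", "", f"scoring failed: {exc}")],
                        model_version=MODEL_VERSION,
                        timestamp=self.trained_at,
                    )
                )
        summary = batch_summary([r.score for r in reports if not math.isnan(r.score)])
        return reports, summary

    def _score_row(
        self,
        table: RecordTable,
        imputed: RecordTable,
        disc: RecordTable,
        imp_mask: pd.DataFrame,
        null_mask: pd.DataFrame,
        num_frame: pd.DataFrame,
        i: int,
        rid: str,
    ) -> RecordQualityReport:
        findings: list[CellFinding] = []
        subscores: dict[str, float] = {}

        # completeness (over all dictionary columns, before imputation)
        row_nulls = {c: bool(null_mask[c].iloc[i]) for c in table.df.columns}
        subscores["completeness"] = record_completeness(self.completeness, row_nulls)
        for c, is_null in row_nulls.items():
            if is_null:
                findings.append(CellFinding("completeness", c, f"{c} is missing"))

        # expert rules on the raw normalized record
        raw_row = table.row_record(i)
        results = evaluate_rules(self.rules, raw_row)
        rs = rule_subscores(results)
        subscores["rules_conformance"] = rs["conformance"]
        subscores["rules_plausibility"] = rs["rule_plausibility"]
        for r in results:
            if r.status == "fail":
                findings.append(CellFinding(f"rule:{r.rule_id}", "", r.message))

        # Bayesian network plausibility (imputed cells never scored)
        row_states = {c: str(disc.df[c].iloc[i]) for c in self.bn_columns}
        row_imputed = {c: bool(imp_mask[c].iloc[i]) for c in self.bn_columns}
        cells, unseen = bnmod.score_cells(self.net, row_states, row_imputed)
        subscores["bn"] = (
            float(np.mean([c.normalized_score for c in cells])) if cells else 1.0
        )
        for col in unseen:
            findings.append(
                CellFinding(
                    "bn_conformance",
                    col,
                    f"{col}={raw_row.get(col)!r} is not a known state; "
                    "dropped from Bayesian-network evidence",
                )
            )
        for c in cells:
            if c.normalized_score < 0.05:
                findings.append(
                    CellFinding(
                        "bn",
                        c.column,
                        f"{c.column}={c.registered_state} has posterior probability "
                        f"{c.probability:.4f} given the rest of the row "
                        f"(most plausible: {c.mode_state}, {c.mode_probability:.4f})",
                        score=c.normalized_score,
                    )
                )

        # contextual outlier trees (raw values; missing split features stop descent)
        ctx_row = {}
        for c in self.preprocess.dictionary.names:
            spec = self.preprocess.dictionary[c]
            if spec.is_numeric:
                v = num_frame[c].iloc[i] if c in num_frame.columns else float("nan")
                ctx_row[c] = float(v) if not pd.isna(v) else float("nan")
            else:
                v = table.df[c].iloc[i] if c in table.df.columns else None
                ctx_row[c] = None if pd.isna(v) else str(v)
        evaluated = flagged = 0
        for target, tree in self.trees.items():
            finding = out.flag_context(tree, ctx_row)
            if finding is None:
                continue
            evaluated += 1
            if finding.flagged:
                flagged += 1
                findings.append(
                    CellFinding("context_tree", target, finding.justification)
                )
        subscores["context_tree"] = 1.0 - flagged / evaluated if evaluated else 1.0

        # IQR bounds on raw observed numeric cells
        n_eval = n_flag = 0
        for col in self.numeric_columns:
            if col not in self.iqr.per_column:
                continue
            v = ctx_row.get(col)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                continue
            n_eval += 1
            if out.flag_iqr(self.iqr, col, v):
                n_flag += 1
                b = self.iqr.per_column[col]
                findings.append(
                    CellFinding(
                        "iqr", col,
                        f"{col}={v:g} outside [{b.lower:g}, {b.upper:g}]",
                        score=float(v),
                    )
                )
        subscores["iqr"] = 1.0 - n_flag / n_eval if n_eval else 1.0

        # multivariate row detectors on the imputed numeric vector
        vec = imputed.df[self.numeric_columns].iloc[i].to_numpy(dtype=float)
        env_flag, d2 = out.flag_envelope(self.envelope, vec)
        subscores["envelope"] = 0.0 if env_flag else 1.0
        if env_flag:
            findings.append(
                CellFinding(
                    "envelope", "",
                    f"squared Mahalanobis distance {d2:.1f} exceeds "
                    f"cutoff {self.envelope.cutoff:.1f}",
                    score=d2,
                )
            )
        lof_flag, factor = out.flag_lof(self.lof, vec)
        subscores["lof"] = 0.0 if lof_flag else 1.0
        if lof_flag:
            findings.append(
                CellFinding(
                    "lof", "",
                    f"local outlier factor {factor:.2f} exceeds "
                    f"threshold {self.lof.threshold:g}",
                    score=factor,
                )
            )

        return RecordQualityReport(
            record_id=rid,
            subscores=subscores,
            score=fuse(subscores, self.weights),
            findings=findings,
            model_version=MODEL_VERSION,
            timestamp=self.trained_at,
        )

    # -------------------------------------------------------------- persist
    def save(self, directory) -> None:
        os.makedirs(directory, exist_ok=True)
        j = lambda name, obj: json.dump(
            obj, open(os.path.join(directory, name), "w"), indent=None
        )
        self.preprocess.save(os.path.join(directory, "preprocess.yaml"))
        j("completeness.json", self.completeness.to_dict())
        j("bn.json", {"columns": self.bn_columns, "net": self.net.to_dict()})
        j("iqr.json", self.iqr.to_dict())
        j("envelope.json", self.envelope.to_dict())
        j("lof.json", self.lof.to_dict())
        j("trees.json", {t: out.tree_to_dict(tr) for t, tr in self.trees.items()})
        j("weights.json", self.weights.to_dict())
        j(
            "meta.json",
            {
                "model_version": MODEL_VERSION,
                "seed": self.seed,
                "trained_at": self.trained_at,
                "numeric_columns": self.numeric_columns,
                "weights_digest": self.weights.digest(),
            },
        )
        import yaml as _yaml

        with open(os.path.join(directory, "rules.yaml"), "w") as fh:
            _yaml.safe_dump(
                {
                    "rules": [
                        {"id": r.id, "dimension": r.dimension, "description": r.description,
                         "kind": r.kind, **r.params}
                        for r in self.rules
                    ]
                },
                fh,
                sort_keys=False,
            )
        with open(os.path.join(directory, "dictionary.yaml"), "w") as fh:
            _yaml.safe_dump(
                {"columns": [c.to_dict() for c in self.dictionary.columns]}, fh, sort_keys=False
            )

    @classmethod
    def load(cls, directory) -> "QualityEngine":
        import yaml as _yaml

        from .records_io import ColumnSpec

        read = lambda name: json.load(open(os.path.join(directory, name)))
        with open(os.path.join(directory, "dictionary.yaml")) as fh:
            dictionary = DataDictionary(
                tuple(ColumnSpec.from_dict(c) for c in _yaml.safe_load(fh)["columns"])
            )
        bn_blob = read("bn.json")
        meta = read("meta.json")
        return cls(
            dictionary=dictionary,
            preprocess=PreprocessModel.load(os.path.join(directory, "preprocess.yaml")),
            completeness=CompletenessModel.from_dict(read("completeness.json")),
            net=bnmod.DiscreteBayesNet.from_dict(bn_blob["net"]),
            bn_columns=list(bn_blob["columns"]),
            iqr=out.IQRBounds.from_dict(read("iqr.json")),
            envelope=out.EnvelopeModel.from_dict(read("envelope.json")),
            lof=out.LOFModel.from_dict(read("lof.json")),
            trees={t: out.tree_from_dict(d) for t, d in read("trees.json").items()},
            rules=load_rules(os.path.join(directory, "rules.yaml")),
            weights=ScoreWeights.from_dict(read("weights.json")),
            seed=int(meta["seed"]),
            trained_at=meta["trained_at"],
            numeric_columns=list(meta["numeric_columns"]),
        )
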