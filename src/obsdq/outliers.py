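"""Marginal and contextual outlier detectors for the plausibility dimension.

Four detectors with different granularity and assumptions:

* IQR bounds (cell-level, marginal): flag values strictly outside
  [Q1 - 3*IQR, Q3 + 3*IQR], bounds inclusive.
* Elliptic envelope (row-level, multivariate Gaussian): flag rows whose
  squared Mahalanobis distance exceeds the chi-square quantile at the
  configured confidence.  Plain Gaussian MLE with a small ridge, on
  z-standardized numeric columns.
* Local outlier factor (row-level, density-based): flag rows whose LOF
  exceeds a threshold (default 1.5), also on standardized numerics.
* Contextual outlier tree (cell-level): a greedy decision tree per target
  column; each branch is treated as a homogeneous cluster, and a cell is
  flagged only if it falls outside the branch's confidence interval AND is
  separated from the branch's data by a large gap — every flag carries the
  branch's split conditions as a human-readable justification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import LocalOutlierFactor

from .records_io import RecordTable

# ---------------------------------------------------------------------------
# IQR bounds


@dataclass(frozen=True)
class ColumnIQR:
    q1: float
    q3: float
    iqr: float
    lower: float
    upper: float


@dataclass
class IQRBounds:
    per_column: dict[str, ColumnIQR]

    def to_dict(self) -> dict:
        return {c: vars(b) for c, b in self.per_column.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "IQRBounds":
        return cls({c: ColumnIQR(**v) for c, v in d.items()})


def fit_iqr(train: RecordTable, columns: list[str] | None = None) -> IQRBounds:
    """Fit per-column bounds Q1 - 3*IQR .. Q3 + 3*IQR on observed values."""
    columns = columns or train.dictionary.numeric_columns()
    out = {}
    for col in columns:
        if not train.dictionary[col].is_numeric:
            raise ValueError(f"IQR bounds require a numeric column, got {col!r}")
        obs = train.numeric_values(col).dropna().to_numpy()
        if obs.size < 4:
            continue
        q1, q3 = np.quantile(obs, [0.25, 0.75], method="linear")
        iqr = q3 - q1
        out[col] = ColumnIQR(float(q1), float(q3), float(iqr),
                             float(q1 - 3 * iqr), float(q3 + 3 * iqr))
    return IQRBounds(out)


def flag_iqr(bounds: IQRBounds, column: str, value: float) -> bool:
    """True iff the value lies strictly outside the bounds (bounds inclusive)."""
    b = bounds.per_column[column]
    return bool(value < b.lower or value > b.upper)


# ---------------------------------------------------------------------------
# z-standardization shared by envelope and LOF


@dataclass
class Standardizer:
    columns: list[str]
    mean: np.ndarray
    sd: np.ndarray  # zeros replaced by 1 (constant columns stay at z=0)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) / self.sd

    def to_dict(self) -> dict:
        return {"columns": self.columns, "mean": self.mean.tolist(), "sd": self.sd.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        return cls(list(d["columns"]), np.asarray(d["mean"]), np.asarray(d["sd"]))


def fit_standardizer(matrix: np.ndarray, columns: list[str]) -> Standardizer:
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return Standardizer(list(columns), mean, sd)


# ---------------------------------------------------------------------------
# elliptic envelope (Gaussian MLE + ridge + chi-square cutoff)


@dataclass
class EnvelopeModel:
    standardizer: Standardizer
    mean: np.ndarray  # in standardized space
    precision: np.ndarray
    cutoff: float  # chi-square quantile
    confidence: float

    def to_dict(self) -> dict:
        return {
            "standardizer": self.standardizer.to_dict(),
            "mean": self.mean.tolist(),
            "precision": self.precision.tolist(),
            "cutoff": self.cutoff,
            "confidence": self.confidence,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnvelopeModel":
        return cls(Standardizer.from_dict(d["standardizer"]), np.asarray(d["mean"]),
                   np.asarray(d["precision"]), float(d["cutoff"]), float(d["confidence"]))


def fit_envelope(
    train_numeric: np.ndarray, columns: list[str], confidence: float = 0.99
) -> EnvelopeModel:
    """Gaussian envelope on standardized numerics; cutoff = chi2.ppf(conf, d)."""
    x = np.asarray(train_numeric, dtype=float)
    n, d = x.shape
    if n < d + 2:
        raise ValueError(
            f"need at least d+2={d + 2} rows for {d} columns; "
            "consider a smaller column subset"
        )
    std = fit_standardizer(x, columns)
    z = std.transform(x)
    mean = z.mean(axis=0)
    cov = np.cov(z, rowvar=False, ddof=0).reshape(d, d)
    cov = cov + np.eye(d) * (1e-6 * np.trace(cov) / d)
    precision = np.linalg.inv(cov)
    return EnvelopeModel(std, mean, precision, float(stats.chi2.ppf(confidence, d)), confidence)


def flag_envelope(model: EnvelopeModel, row_values: np.ndarray) -> tuple[bool, float]:
    """(flagged, squared Mahalanobis distance) for one raw numeric row."""
    z = model.standardizer.transform(row_values) - model.mean
    d2 = float(z @ model.precision @ z)
    return d2 > model.cutoff, d2


# ---------------------------------------------------------------------------
# local outlier factor (sklearn behind the module surface)


@dataclass
class LOFModel:
    standardizer: Standardizer
    k: int
    threshold: float
    _lof: LocalOutlierFactor | None = None
    reference: np.ndarray | None = None  # standardized training rows

    def ensure_fitted(self) -> LocalOutlierFactor:
        if self._lof is None:
            lof = LocalOutlierFactor(n_neighbors=self.k, novelty=True)
            lof.fit(self.reference)
            self._lof = lof
        return self._lof

    def to_dict(self) -> dict:
        return {
            "standardizer": self.standardizer.to_dict(),
            "k": self.k,
            "threshold": self.threshold,
            "reference": np.asarray(self.reference).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LOFModel":
        return cls(Standardizer.from_dict(d["standardizer"]), int(d["k"]),
                   float(d["threshold"]), None, np.asarray(d["reference"]))


def fit_lof(
    train_numeric: np.ndarray, columns: list[str], k: int = 20, threshold: float = 1.5
) -> LOFModel:
    x = np.asarray(train_numeric, dtype=float)
    if k < 1 or k >= len(x):
        raise ValueError(f"k={k} must satisfy 1 <= k < n={len(x)}")
    n_unique = len(np.unique(x, axis=0))
    if n_unique <= k:
        raise ValueError(
            f"only {n_unique} distinct training rows for k={k}; reduce k"
        )
    std = fit_standardizer(x, columns)
    model = LOFModel(std, k, threshold, None, std.transform(x))
    model.ensure_fitted()
    return model


def flag_lof(model: LOFModel, row_values: np.ndarray) -> tuple[bool, float]:
    """(flagged, LOF factor) for one raw numeric row; factor ~1 for inliers."""
    lof = model.ensure_fitted()
    z = model.standardizer.transform(np.asarray(row_values, dtype=float)).reshape(1, -1)
    factor = float(-lof.score_samples(z)[0])
    return factor > model.threshold, factor


# ---------------------------------------------------------------------------
# contextual outlier tree


@dataclass
class TreeNode:
    """One branch of the contextual tree, with its target summary."""

    n: int
    # numeric-target summary
    mean: float | None = None
    sd: float | None = None
    sorted_values: np.ndarray | None = None  # unique observed target values
    # categorical-target summary
    proportions: dict[str, float] | None = None
    # split (internal nodes only)
    feature: str | None = None
    split_kind: str | None = None  # "num" (<= threshold) or "cat" (== category)
    threshold: float | None = None
    category: str | None = None
    left: "TreeNode | None" = None  # condition true
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


@dataclass(frozen=True)
class ContextFinding:
    column: str
    value: object
    flagged: bool
    conditions: tuple[str, ...]  # conjunction defining the branch
    bounds: tuple[float, float] | None  # numeric CI, if applicable
    justification: str


@dataclass
class ContextTree:
    target: str
    target_kind: str  # "num" | "cat"
    root: TreeNode | None  # None for constant targets (no flags possible)
    conf: float
    gap_mult: float
    max_depth: int
    min_branch: int
    feature_kinds: dict[str, str]  # predictor -> "num" | "cat"


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - (p * p).sum())


def _best_split_numeric_feature(
    x: np.ndarray, y_num: np.ndarray | None, y_codes: np.ndarray | None,
    n_classes: int, min_branch: int,
) -> tuple[float, float] | None:
    """Best (impurity decrease, threshold) scanning midpoints via prefix sums."""
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(xs)
    # candidate boundaries: positions where the sorted feature changes value
    change = np.nonzero(np.diff(xs) > 0)[0]  # split after index i
    if change.size == 0:
        return None
    valid = change[(change + 1 >= min_branch) & (n - change - 1 >= min_branch)]
    if valid.size == 0:
        return None
    if y_num is not None:
        ys = y_num[order]
        c1 = np.cumsum(ys)
        c2 = np.cumsum(ys * ys)
        nl = valid + 1.0
        nr = n - nl
        sse_l = c2[valid] - c1[valid] ** 2 / nl
        sse_r = (c2[-1] - c2[valid]) - (c1[-1] - c1[valid]) ** 2 / nr
        total_sse = c2[-1] - c1[-1] ** 2 / n
        gain = total_sse - (sse_l + sse_r)
    else:
        yc = y_codes[order]
        onehot = np.zeros((n, n_classes))
        onehot[np.arange(n), yc] = 1.0
        cum = np.cumsum(onehot, axis=0)
        nl = (valid + 1.0)[:, None]
        pl = cum[valid] / nl
        pr = (cum[-1] - cum[valid]) / (n - nl)
        gini_l = 1.0 - (pl * pl).sum(axis=1)
        gini_r = 1.0 - (pr * pr).sum(axis=1)
        parent = _gini(cum[-1])
        gain = parent - (nl[:, 0] / n) * gini_l - ((n - nl[:, 0]) / n) * gini_r
    best = int(np.argmax(gain))
    if gain[best] <= 1e-12:
        return None
    i = valid[best]
    thr = 0.5 * (xs[i] + xs[i + 1])  # midpoint between sorted unique values
    return float(gain[best]), float(thr)


def _best_split_categorical_feature(
    x: np.ndarray, y_num: np.ndarray | None, y_codes: np.ndarray | None,
    n_classes: int, min_branch: int,
) -> tuple[float, str] | None:
    """Best one-vs-rest split over the feature's categories."""
    n = len(x)
    best: tuple[float, str] | None = None
    for cat in sorted(pd.unique(x).tolist()):
        mask = x == cat
        nl = int(mask.sum())
        if nl < min_branch or n - nl < min_branch:
            continue
        if y_num is not None:
            yl, yr = y_num[mask], y_num[~mask]
            sse = lambda v: float(((v - v.mean()) ** 2).sum()) if len(v) else 0.0
            gain = sse(y_num) - sse(yl) - sse(yr)
        else:
            cl = np.bincount(y_codes[mask], minlength=n_classes).astype(float)
            cr = np.bincount(y_codes[~mask], minlength=n_classes).astype(float)
            parent = _gini(cl + cr)
            gain = parent - (nl / n) * _gini(cl) - ((n - nl) / n) * _gini(cr)
        if gain > 1e-12 and (best is None or gain > best[0]):
            best = (float(gain), str(cat))
    return best


def _node_summary(
    y_num: np.ndarray | None, y_cat: np.ndarray | None
) -> TreeNode:
    if y_num is not None:
        return TreeNode(
            n=len(y_num),
            mean=float(y_num.mean()),
            sd=float(y_num.std(ddof=0)),
            sorted_values=np.unique(y_num),
        )
    vals, counts = np.unique(y_cat, return_counts=True)
    props = {str(v): float(c) / len(y_cat) for v, c in zip(vals, counts)}
    return TreeNode(n=len(y_cat), proportions=props)


def fit_context_tree(
    train: RecordTable,
    target: str,
    predictors: list[str] | None = None,
    max_depth: int = 4,
    min_branch: int = 50,
    conf: float = 0.99,
    gap_mult: float = 1.5,
) -> ContextTree:
    """Grow a greedy tree predicting ``target`` from the other columns.

    Numeric targets use variance reduction, categorical targets Gini.  The
    tree never uses its own target as a predictor.  A constant target yields
    an empty tree (no flags possible).  Expects an imputed table.
    """
    if len(train) == 0:
        raise ValueError("empty training table")
    dictionary = train.dictionary
    spec = dictionary[target]
    target_kind = "num" if spec.is_numeric else "cat"
    if predictors is None:
        predictors = [
            c.name for c in dictionary.columns
            if c.name != target and c.kind not in ("identifier", "date")
        ]
    predictors = [p for p in predictors if p != target]
    feature_kinds = {p: ("num" if dictionary[p].is_numeric else "cat") for p in predictors}

    if target_kind == "num":
        y_num = train.numeric_values(target).to_numpy(dtype=float)
        y_codes, y_raw, classes = None, None, []
    else:
        y_raw = train.df[target].astype(str).to_numpy()
        classes = sorted(pd.unique(y_raw).tolist())
        lut = {c: i for i, c in enumerate(classes)}
        y_codes = np.asarray([lut[v] for v in y_raw])
        y_num = None
    n_classes = len(classes)

    if (y_num is not None and np.unique(y_num).size <= 1) or (
        y_codes is not None and n_classes <= 1
    ):
        return ContextTree(target, target_kind, None, conf, gap_mult,
                           max_depth, min_branch, feature_kinds)

    feats: dict[str, np.ndarray] = {}
    for p in predictors:
        if feature_kinds[p] == "num":
            feats[p] = train.numeric_values(p).to_numpy(dtype=float)
        else:
            feats[p] = train.df[p].astype(str).to_numpy()

    def grow(idx: np.ndarray, depth: int) -> TreeNode:
        yn = y_num[idx] if y_num is not None else None
        yc = y_codes[idx] if y_codes is not None else None
        node = _node_summary(yn, y_raw[idx] if y_raw is not None else None)
        if depth >= max_depth or len(idx) < 2 * min_branch:
            return node
        best = None  # (gain, feature, kind, param); ties -> first in dict order
        for p in predictors:
            fx = feats[p][idx]
            if feature_kinds[p] == "num":
                res = _best_split_numeric_feature(fx, yn, yc, n_classes, min_branch)
                if res and (best is None or res[0] > best[0] + 1e-12):
                    best = (res[0], p, "num", res[1])
            else:
                res = _best_split_categorical_feature(fx, yn, yc, n_classes, min_branch)
                if res and (best is None or res[0] > best[0] + 1e-12):
                    best = (res[0], p, "cat", res[1])
        if best is None:
            return node
        _, p, kind, param = best
        fx = feats[p][idx]
        if kind == "num":
            mask = fx <= param
            node.feature, node.split_kind, node.threshold = p, "num", float(param)
        else:
            mask = fx == param
            node.feature, node.split_kind, node.category = p, "cat", str(param)
        node.left = grow(idx[mask], depth + 1)
        node.right = grow(idx[~mask], depth + 1)
        return node

    root = grow(np.arange(len(train)), 0)
    return ContextTree(target, target_kind, root, conf, gap_mult,
                       max_depth, min_branch, feature_kinds)


def _descend(tree: ContextTree, row: dict) -> tuple[TreeNode, list[str]]:
    node = tree.root
    conds: list[str] = []
    while not node.is_leaf:
        v = row.get(node.feature)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            break  # missing split feature: evaluate against the current branch
        if node.split_kind == "num":
            try:
                vf = float(v)
            except (TypeError, ValueError):
                break
            if vf <= node.threshold:
                conds.append(f"{node.feature} <= {node.threshold:g}")
                node = node.left
            else:
                conds.append(f"{node.feature} > {node.threshold:g}")
                node = node.right
        else:
            if str(v) == node.category:
                conds.append(f"{node.feature} == {node.category}")
                node = node.left
            else:
                conds.append(f"{node.feature} != {node.category}")
                node = node.right
    return node, conds


def flag_context(tree: ContextTree, row: dict) -> ContextFinding | None:
    """Evaluate one record's target cell against its branch distribution.

    Numeric targets: flagged iff the value is outside mean +/- z(conf)*sd AND
    the gap to the nearest in-branch training value on the same side is at
    least gap_mult * branch sd.  Categorical: flagged iff the value's
    within-branch proportion is below 1-conf while the branch is dominated by
    a modal category (proportion >= 0.5).
    """
    if tree.root is None:
        return None
    value = row.get(tree.target)
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    node, conds = _descend(tree, row)
    cond_txt = " AND ".join(conds) if conds else "(root branch)"

    if tree.target_kind == "num":
        try:
            v = float(value)
        except (TypeError, ValueError):
            return None
        z = stats.norm.ppf(0.5 + tree.conf / 2)
        lo, hi = node.mean - z * node.sd, node.mean + z * node.sd
        flagged = False
        if v < lo or v > hi:
            sv = node.sorted_values
            if v > hi:
                below = sv[sv <= v]
                gap = v - below[-1] if below.size else math.inf
            else:
                above = sv[sv >= v]
                gap = above[0] - v if above.size else math.inf
            flagged = gap >= tree.gap_mult * node.sd
        just = (
            f"{tree.target}={v:g} vs branch [{lo:g}, {hi:g}] "
            f"(n={node.n}, mean={node.mean:g}, sd={node.sd:g}) under {cond_txt}"
        )
        return ContextFinding(tree.target, v, flagged, tuple(conds), (float(lo), float(hi)), just)

    props = node.proportions
    p = props.get(str(value), 0.0)
    modal = max(props.values()) if props else 0.0
    flagged = p < (1 - tree.conf) and modal >= 0.5
    just = (
        f"{tree.target}={value!s} has within-branch proportion {p:.4f} "
        f"(modal {modal:.2f}, n={node.n}) under {cond_txt}"
    )
    return ContextFinding(tree.target, value, flagged, tuple(conds), None, just)


# ---------------------------------------------------------------------------
# context-tree serialization


def _node_to_dict(node: TreeNode | None) -> dict | None:
    if node is None:
        return None
    return {
        "n": node.n,
        "mean": node.mean,
        "sd": node.sd,
        "sorted_values": None if node.sorted_values is None else node.sorted_values.tolist(),
        "proportions": node.proportions,
        "feature": node.feature,
        "split_kind": node.split_kind,
        "threshold": node.threshold,
        "category": node.category,
        "left": _node_to_dict(node.left),
        "right": _node_to_dict(node.right),
    }


def _node_from_dict(d: dict | None) -> TreeNode | None:
    if d is None:
        return None
    return TreeNode(
        n=d["n"],
        mean=d["mean"],
        sd=d["sd"],
        sorted_values=None if d["sorted_values"] is None else np.asarray(d["sorted_values"]),
        proportions=d["proportions"],
        feature=d["feature"],
        split_kind=d["split_kind"],
        threshold=d["threshold"],
        category=d["category"],
        left=_node_from_dict(d["left"]),
        right=_node_from_dict(d["right"]),
    )


def tree_to_dict(tree: ContextTree) -> dict:
    return {
        "target": tree.target,
        "target_kind": tree.target_kind,
        "root": _node_to_dict(tree.root),
        "conf": tree.conf,
        "gap_mult": tree.gap_mult,
        "max_depth": tree.max_depth,
        "min_branch": tree.min_branch,
        "feature_kinds": tree.feature_kinds,
    }


def tree_from_dict(d: dict) -> ContextTree:
    return ContextTree(
        d["target"], d["target_kind"], _node_from_dict(d["root"]),
        float(d["conf"]), float(d["gap_mult"]), int(d["max_depth"]),
        int(d["min_branch"]), dict(d["feature_kinds"]),
    )
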