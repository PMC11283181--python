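"""Evaluation machinery: repeated cross-validated per-column AUROC for the
Bayesian network, rank agreement with human assessors, and threshold-based
bad/good-record classification AUROC.

The per-column AUROC treats the registered (discretized) value of the target
as the true class and the network's posterior given the rest of the row as
the prediction; multiclass targets are scored as one-vs-rest macro-averaged
AUROC.  A column truly independent of the others should sit at chance
(~0.5), a strongly dependent one near 1 — the sanity pattern a multi-column
clinical table is expected to show.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import bn as bnmod
from .preprocess import apply_preprocess, discretize, fit_preprocess
from .records_io import RecordTable


@dataclass
class ColumnCV:
    column: str
    mean_auroc: float
    ci_low: float
    ci_high: float
    n_rows: int
    fold_scores: list[float]


@dataclass
class RankComparison:
    assessor_rankings: np.ndarray  # (n_assessors, n_records), 1 = best
    model_scores: np.ndarray
    spearman_per_assessor: list[float]
    spearman_pvalues: list[float]
    average_spearman: float
    kendall_tau: float
    kendall_pvalue: float
    alpha: float = 0.05


def binary_auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Trapezoidal AUROC with midrank tie handling (higher score = positive)."""
    return float(roc_auc_score(np.asarray(labels, dtype=int), np.asarray(scores, dtype=float)))


def macro_ovr_auroc(
    y_true: np.ndarray, probs: np.ndarray, classes: list[str],
    train_classes: set[str] | None = None,
) -> float | None:
    """One-vs-rest macro average; classes absent from training are excluded."""
    scores = []
    for k, cls in enumerate(classes):
        if train_classes is not None and cls not in train_classes:
            continue
        pos = y_true == cls
        if pos.all() or not pos.any():
            continue
        scores.append(binary_auroc(probs[:, k], pos))
    return float(np.mean(scores)) if scores else None


def _t_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    m = float(values.mean())
    if len(values) < 2 or values.std(ddof=1) == 0:
        return m, m
    half = stats.t.ppf(0.5 + level / 2, len(values) - 1) * values.std(ddof=1) / np.sqrt(len(values))
    return m - float(half), m + float(half)


def repeated_cv_auroc(
    table: RecordTable,
    columns: list[str] | None = None,
    splits: int = 10,
    repeats: int = 2,
    seed: int = 0,
    max_parents: int = 3,
    restarts: int = 1,
    missing_threshold: float = 0.8,
) -> list[ColumnCV]:
    """Repeated stratified k-fold AUROC with each column as the target.

    For each target, only rows where the target was originally observed are
    used.  Every fold retrains the full pipeline (preprocessing, structure,
    CPTs) on the training rows and predicts the held-out rows' posterior
    given all their other observed, non-imputed cells.
    """
    if columns is None:
        columns = [
            c.name for c in table.dictionary.columns if c.kind not in ("identifier", "date")
        ]
    null_mask = table.null_mask()
    results = []
    for target in columns:
        use = np.nonzero(~null_mask[target].to_numpy())[0]
        sub = RecordTable(
            table.dictionary,
            table.df.iloc[use].reset_index(drop=True),
            table.malformed.iloc[use].reset_index(drop=True),
            table.provenance,
        )
        strata = sub.df[target].astype(str).to_numpy()
        fold_scores = []
        for rep in range(repeats):
            skf = StratifiedKFold(n_splits=splits, shuffle=True,
                                  random_state=(seed + 1000 * rep) % (2**31))
            for tr_idx, te_idx in skf.split(np.zeros(len(sub)), strata):
                score = _one_fold(sub, target, tr_idx, te_idx, seed,
                                  max_parents, restarts, missing_threshold)
                if score is not None:
                    fold_scores.append(score)
        arr = np.asarray(fold_scores)
        lo, hi = _t_ci(arr)
        results.append(ColumnCV(target, float(arr.mean()), lo, hi, len(sub), fold_scores))
    return results


def _one_fold(
    sub: RecordTable, target: str, tr_idx, te_idx, seed, max_parents, restarts,
    missing_threshold,
) -> float | None:
    train = RecordTable(
        sub.dictionary,
        sub.df.iloc[tr_idx].reset_index(drop=True),
        sub.malformed.iloc[tr_idx].reset_index(drop=True),
    )
    test = RecordTable(
        sub.dictionary,
        sub.df.iloc[te_idx].reset_index(drop=True),
        sub.malformed.iloc[te_idx].reset_index(drop=True),
    )
    pre = fit_preprocess(train, missing_threshold)
    if target not in pre.dictionary:
        return None  # target itself dropped for missingness
    imputed_tr, _ = apply_preprocess(pre, train)
    disc_tr = discretize(pre, imputed_tr)
    bn_cols = [
        c.name for c in pre.dictionary.columns
        if c.kind not in ("identifier", "date")
        and disc_tr.df[c.name].astype(str).nunique() <= 30
    ]
    if target not in bn_cols or len(bn_cols) < 2:
        return None
    structure = bnmod.learn_structure(
        disc_tr.df[bn_cols], max_parents=max_parents, seed=seed, restarts=restarts
    )
    net = bnmod.fit_cpts(structure, disc_tr.df[bn_cols])

    imputed_te, imp_mask = apply_preprocess(pre, test)
    disc_te = discretize(pre, imputed_te)
    test_nulls = test.null_mask()
    classes = net.states[target]
    probs = np.zeros((len(test), len(classes)))
    y_true = np.empty(len(test), dtype=object)
    for i in range(len(test)):
        evidence = {}
        for c in bn_cols:
            if c == target:
                continue
            if imp_mask[c].iloc[i] or test_nulls[c].iloc[i]:
                continue
            state = str(disc_te.df[c].iloc[i])
            if net.state_index(c, state) is not None:
                evidence[c] = state
        post = bnmod.posterior(net, evidence, target)
        probs[i] = [post[s] for s in classes]
        y_true[i] = str(disc_te.df[target].iloc[i])
    return macro_ovr_auroc(y_true, probs, classes, set(classes))


def rank_agreement(
    model_scores: np.ndarray, assessor_rankings: np.ndarray, alpha: float = 0.05
) -> RankComparison:
    """Agreement between the tool's scores and human quality rankings.

    Assessor rankings use 1 = best; the model ranking is descending score
    order (highest score ranked 1).  Spearman is computed per assessor and
    averaged; Kendall's tau is computed against the mean assessor ranking.
    """
    scores = np.asarray(model_scores, dtype=float)
    ranks = np.atleast_2d(np.asarray(assessor_rankings, dtype=float))
    if ranks.shape[1] != len(scores):
        raise ValueError(
            f"{ranks.shape[1]} ranked records but {len(scores)} model scores"
        )
    if len(scores) < 2:
        raise ValueError("need at least 2 records")
    model_rank = stats.rankdata(-scores)  # midranks on ties
    rhos, ps = [], []
    for a in ranks:
        rho, p = stats.spearmanr(model_rank, a)
        rhos.append(float(rho))
        ps.append(float(p))
    mean_rank = ranks.mean(axis=0)
    tau, tau_p = stats.kendalltau(model_rank, mean_rank)
    return RankComparison(
        assessor_rankings=ranks,
        model_scores=scores,
        spearman_per_assessor=rhos,
        spearman_pvalues=ps,
        average_spearman=float(np.mean(rhos)),
        kendall_tau=float(tau),
        kendall_pvalue=float(tau_p),
        alpha=alpha,
    )


def threshold_auroc(
    model_scores: np.ndarray,
    mean_ranks: np.ndarray,
    thresholds: tuple[float, ...] = (3, 4, 5, 6),
) -> dict[float, float | None]:
    """AUROC of (1 - score) as a bad-record classifier per rank threshold.

    A record is labelled bad when its mean assessor rank is >= the
    threshold.  Thresholds yielding a single class map to None.
    """
    scores = np.asarray(model_scores, dtype=float)
    ranks = np.asarray(mean_ranks, dtype=float)
    out: dict[float, float | None] = {}
    for t in thresholds:
        bad = ranks >= t
        if bad.all() or not bad.any():
            out[float(t)] = None
            continue
        out[float(t)] = binary_auroc(1.0 - scores, bad)
    return out
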