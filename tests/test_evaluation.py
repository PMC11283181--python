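import itertools

import numpy as np
import pandas as pd
import pytest

from obsdq.evaluation import (
    binary_auroc,
    macro_ovr_auroc,
    rank_agreement,
    repeated_cv_auroc,
    threshold_auroc,
)
from obsdq.records_io import ColumnSpec, DataDictionary, normalize_table


def mann_whitney_auroc(scores, labels):
    """Pair-counting oracle: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def kendall_tau_oracle(a, b):
    """tau = 2(C - D) / (n(n-1)) by brute-force pair enumeration (no ties)."""
    n = len(a)
    c = d = 0
    for i, j in itertools.combinations(range(n), 2):
        s = (a[i] - a[j]) * (b[i] - b[j])
        c += s > 0
        d += s < 0
    return 2 * (c - d) / (n * (n - 1))


def spearman_oracle(a, b):
    """Pearson correlation of the rank vectors (permutations, no ties)."""
    ra, rb = np.argsort(np.argsort(a)), np.argsort(np.argsort(b))
    ra, rb = ra - ra.mean(), rb - rb.mean()
    return float((ra * rb).sum() / np.sqrt((ra**2).sum() * (rb**2).sum()))


class TestAUROC:
    def test_matches_mann_whitney_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            n = int(rng.integers(4, 25))
            labels = np.zeros(n, dtype=bool)
            labels[: int(rng.integers(1, n))] = True
            rng.shuffle(labels)
            scores = rng.integers(0, 6, n).astype(float)  # ties on purpose
            if labels.all() or not labels.any():
                continue
            assert binary_auroc(scores, labels) == pytest.approx(
                mann_whitney_auroc(scores, labels), abs=1e-12
            )

    def test_macro_ovr_excludes_untrained_classes(self):
        y = np.array(["a", "a", "b", "b", "c"])
        probs = np.array([
            [0.8, 0.1, 0.5],
            [0.7, 0.2, 0.1],
            [0.1, 0.8, 0.1],
            [0.2, 0.7, 0.1],
            [0.3, 0.3, 0.2],
        ])
        full = macro_ovr_auroc(y, probs, ["a", "b", "c"])
        partial = macro_ovr_auroc(y, probs, ["a", "b", "c"], train_classes={"a", "b"})
        assert full is not None and partial is not None
        assert partial == pytest.approx(1.0)
        assert full < partial  # the imperfect held-out-only class dilutes the mean


def _cv_table(n=2000, seed=0, noise=0.02):
    """A: uniform 3-state; B copies A with small noise; C independent."""
    rng = np.random.default_rng(seed)
    a = rng.choice(["x", "y", "z"], n)
    b = np.where(rng.random(n) < noise, rng.choice(["x", "y", "z"], n), a)
    c = rng.choice(["u", "v", "w"], n)
    specs = tuple(ColumnSpec(k, "categorical") for k in ("a", "b", "c"))
    return normalize_table(pd.DataFrame({"a": a, "b": b, "c": c}), DataDictionary(specs))


class TestRepeatedCV:
    def test_dependent_column_near_perfect_and_independent_at_chance(self):
        table = _cv_table(n=2000, seed=1)
        res = {r.column: r for r in repeated_cv_auroc(table, splits=5, repeats=1, seed=0)}
        assert res["b"].mean_auroc >= 0.95
        assert 0.45 <= res["c"].mean_auroc <= 0.55
        for r in res.values():
            assert r.ci_low <= r.mean_auroc <= r.ci_high

    def test_deterministic_function_target_reaches_auroc_099(self):
        rng = np.random.default_rng(2)
        a = rng.choice(["x", "y", "z"], 2000)
        specs = tuple(ColumnSpec(k, "categorical") for k in ("a", "b"))
        t = normalize_table(pd.DataFrame({"a": a, "b": a}), DataDictionary(specs))
        res = {r.column: r for r in repeated_cv_auroc(t, columns=["b"], splits=5,
                                                      repeats=1, seed=0)}
        assert res["b"].mean_auroc >= 0.99

    def test_reproducible_under_fixed_seed(self):
        table = _cv_table(n=600, seed=3)
        r1 = repeated_cv_auroc(table, splits=4, repeats=1, seed=9)
        r2 = repeated_cv_auroc(table, splits=4, repeats=1, seed=9)
        assert [(a.column, a.fold_scores) for a in r1] == [
            (a.column, a.fold_scores) for a in r2
        ]

    def test_stratified_folds_balance_binary_target(self):
        # 4 rows, balanced binary target, 2 splits -> every fold holds one of each
        from sklearn.model_selection import StratifiedKFold

        y = np.array(["a", "a", "b", "b"])
        skf = StratifiedKFold(n_splits=2, shuffle=True, random_state=0)
        for _, test_idx in skf.split(np.zeros(4), y):
            assert sorted(y[test_idx]) == ["a", "b"]


class TestRankAgreement:
    def test_perfect_agreement_is_one(self):
        scores = np.array([0.9, 0.8, 0.6, 0.4, 0.2])
        ranking = np.array([1, 2, 3, 4, 5], dtype=float)
        cmp = rank_agreement(scores, ranking[None, :])
        assert cmp.average_spearman == pytest.approx(1.0)
        assert cmp.kendall_tau == pytest.approx(1.0)

    def test_reversed_agreement_is_minus_one(self):
        scores = np.array([0.2, 0.4, 0.6, 0.8])
        ranking = np.array([1, 2, 3, 4], dtype=float)
        cmp = rank_agreement(scores, ranking[None, :])
        assert cmp.average_spearman == pytest.approx(-1.0)
        assert cmp.kendall_tau == pytest.approx(-1.0)

    def test_matches_bruteforce_pair_enumeration(self):
        rng = np.random.default_rng(4)
        for n in (4, 5, 6, 8):
            scores = rng.permutation(n).astype(float) + 1
            ranking = (rng.permutation(n).astype(float) + 1)[None, :]
            cmp = rank_agreement(scores, ranking)
            model_rank = n + 1 - np.argsort(np.argsort(scores)) - 1  # rank 1 = max score
            assert cmp.kendall_tau == pytest.approx(
                kendall_tau_oracle(model_rank, ranking[0]), abs=1e-12
            )
            assert cmp.average_spearman == pytest.approx(
                spearman_oracle(model_rank, ranking[0]), abs=1e-12
            )

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            rank_agreement(np.array([0.1, 0.2]), np.array([[1, 2, 3]]))


class TestThresholdAUROC:
    def test_perfect_anti_order_scores_one_everywhere(self):
        scores = np.linspace(1, 0, 10)  # best score first
        mean_ranks = np.arange(1, 11, dtype=float)  # rank 10 = worst
        out = threshold_auroc(scores, mean_ranks)
        assert set(out) == {3.0, 4.0, 5.0, 6.0}
        assert all(v == pytest.approx(1.0) for v in out.values())

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(5)
        scores = rng.random(4000)
        ranks = rng.uniform(1, 10, 4000)
        out = threshold_auroc(scores, ranks, thresholds=(5,))
        assert out[5.0] == pytest.approx(0.5, abs=0.05)

    def test_single_class_threshold_marked_undefined(self):
        scores = np.array([0.9, 0.8, 0.7])
        ranks = np.array([1.0, 2.0, 3.0])  # nobody ranked >= 6
        out = threshold_auroc(scores, ranks, thresholds=(6,))
        assert out[6.0] is None
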