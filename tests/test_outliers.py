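import numpy as np
import pandas as pd
import pytest
from scipy import stats

from obsdq.outliers import (
    fit_context_tree,
    fit_envelope,
    fit_iqr,
    fit_lof,
    flag_context,
    flag_envelope,
    flag_iqr,
    flag_lof,
    tree_from_dict,
    tree_to_dict,
)
from obsdq.records_io import ColumnSpec, DataDictionary, normalize_table


def numeric_table(**cols):
    specs = tuple(ColumnSpec(c, "continuous") for c in cols)
    df = pd.DataFrame({c: np.asarray(v, dtype=float) for c, v in cols.items()})
    return normalize_table(df, DataDictionary(specs))


class TestIQR:
    def test_bounds_match_closed_form(self):
        # quartiles Q1=10, Q3=20 -> bounds [-20, 50]
        vals = np.array([10.0, 10, 10, 15, 20, 20, 20])
        t = numeric_table(x=vals)
        b = fit_iqr(t).per_column["x"]
        assert (b.q1, b.q3) == (10.0, 20.0)
        assert (b.lower, b.upper) == (-20.0, 50.0)
        bounds = fit_iqr(t)
        assert flag_iqr(bounds, "x", 55.0)
        assert not flag_iqr(bounds, "x", 15.0)
        assert not flag_iqr(bounds, "x", 50.0)  # bounds inclusive
        assert not flag_iqr(bounds, "x", -20.0)

    def test_flag_is_pure_function_of_bounds_and_value(self):
        t = numeric_table(x=np.arange(100.0))
        bounds = fit_iqr(t)
        assert [flag_iqr(bounds, "x", v) for v in (0.0, 500.0)] == [False, True]
        assert [flag_iqr(bounds, "x", v) for v in (0.0, 500.0)] == [False, True]

    def test_non_numeric_column_errors(self):
        specs = (ColumnSpec("g", "categorical"),)
        t = normalize_table(pd.DataFrame({"g": ["a", "b", "c", "d"]}), DataDictionary(specs))
        with pytest.raises(ValueError):
            fit_iqr(t, ["g"])


class TestEnvelope:
    def test_center_has_zero_distance_and_no_flag(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, (2000, 1))
        m = fit_envelope(x, ["x"], confidence=0.99)
        flagged, d2 = flag_envelope(m, np.array([x.mean()]))
        assert not flagged
        assert d2 == pytest.approx(0.0, abs=1e-6)

    def test_ten_sigma_point_flagged(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, (2000, 1))
        m = fit_envelope(x, ["x"])
        flagged, d2 = flag_envelope(m, np.array([10.0]))
        assert flagged
        assert d2 > stats.chi2.ppf(0.99, 1)

    def test_train_mean_is_minimal_distance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (500, 3))
        m = fit_envelope(x, list("abc"))
        d_mean = flag_envelope(m, x.mean(axis=0))[1]
        for row in x[:50]:
            assert d_mean <= flag_envelope(m, row)[1] + 1e-9

    def test_too_few_rows_errors(self):
        with pytest.raises(ValueError, match="d\\+2"):
            fit_envelope(np.zeros((3, 4)), list("abcd"))

    def test_false_flag_rate_converges_to_one_minus_confidence(self):
        rng = np.random.default_rng(3)
        train = rng.normal(0, 1, (20000, 3)) @ np.array(
            [[1, 0.4, 0], [0, 1, 0.2], [0, 0, 1.0]]
        )
        m = fit_envelope(train, list("abc"), confidence=0.99)
        # simulate from the *fitted* Gaussian and measure the flag rate
        cov = np.linalg.inv(m.precision)
        z = rng.multivariate_normal(m.mean, cov, size=50000)
        d2 = np.einsum("ij,jk,ik->i", z - m.mean, m.precision, z - m.mean)
        rate = float((d2 > m.cutoff).mean())
        assert rate == pytest.approx(0.01, abs=0.02)


def lof_oracle(train: np.ndarray, query: np.ndarray, k: int) -> float:
    """Brute-force local outlier factor of one query against a training set."""
    def knn(point, exclude=None):
        d = np.linalg.norm(train - point, axis=1)
        if exclude is not None:
            d[exclude] = np.inf
        idx = np.argsort(d, kind="stable")[:k]
        return idx, d[idx]

    def k_dist(i):
        _, dd = knn(train[i], exclude=i)
        return dd[-1]

    def lrd(point, exclude=None):
        idx, dd = knn(point, exclude=exclude)
        reach = np.maximum(dd, [k_dist(j) for j in idx])
        return 1.0 / np.mean(reach)

    idx, _ = knn(query)
    return float(np.mean([lrd(train[j], exclude=j) for j in idx]) / lrd(query))


class TestLOF:
    def test_interior_grid_point_near_one(self):
        g = np.array([[i, j] for i in range(12) for j in range(12)], dtype=float)
        m = fit_lof(g, ["x", "y"], k=8)
        flagged, factor = flag_lof(m, np.array([5.5, 5.5]))
        assert not flagged
        assert 0.8 <= factor <= 1.2

    def test_far_point_flagged(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, (300, 2))
        m = fit_lof(x, ["a", "b"], k=20)
        flagged, factor = flag_lof(m, np.array([100.0, 100.0]))
        assert flagged and factor > 1.5

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(5)
        train = rng.random((60, 2))
        m = fit_lof(train, ["a", "b"], k=5)
        std = m.standardizer
        for q in rng.random((5, 2)):
            _, factor = flag_lof(m, q)
            want = lof_oracle(std.transform(train), std.transform(q), k=5)
            assert factor == pytest.approx(want, rel=1e-6)

    def test_k_out_of_range_errors(self):
        with pytest.raises(ValueError):
            fit_lof(np.random.default_rng(0).random((10, 2)), ["a", "b"], k=10)

    def test_duplicate_collapsed_train_smaller_than_k_errors(self):
        x = np.tile([[1.0, 2.0]], (50, 1))
        with pytest.raises(ValueError, match="distinct"):
            fit_lof(x, ["a", "b"], k=5)


def grouped_table(n=2000, sd=1.0, seed=0):
    rng = np.random.default_rng(seed)
    g = rng.choice(["g1", "g2", "g3"], n)
    mu = {"g1": 0.0, "g2": 50.0, "g3": 100.0}
    y = np.array([mu[x] for x in g]) + rng.normal(0, sd, n)
    specs = (ColumnSpec("grp", "categorical"), ColumnSpec("y", "continuous"))
    df = pd.DataFrame({"grp": g, "y": y})
    return normalize_table(df, DataDictionary(specs))


class TestContextTree:
    def test_zero_noise_groups_give_zero_sd_branches(self):
        t = grouped_table(n=600, sd=0.0)
        tree = fit_context_tree(t, "y", min_branch=30)
        node, conds = tree.root, []
        assert node.feature == "grp"
        # walk to any leaf: sd must be 0
        while not node.is_leaf:
            node = node.left
        assert node.sd == pytest.approx(0.0)

    def test_clean_data_not_flagged_inside_ci(self):
        t = grouped_table(n=2000, sd=1.0, seed=1)
        tree = fit_context_tree(t, "y", min_branch=50)
        f = flag_context(tree, {"grp": "g2", "y": 50.5})
        assert f is not None and not f.flagged

    def test_contextual_contaminant_flagged_with_branch_justification(self):
        t = grouped_table(n=2000, sd=1.0, seed=2)
        tree = fit_context_tree(t, "y", min_branch=50)
        # y=0 is a perfectly normal g1 value but impossible for g3
        f = flag_context(tree, {"grp": "g3", "y": 0.0})
        assert f is not None and f.flagged
        assert "grp" in f.justification
        assert all("y" != c.split(" ")[0] for c in f.conditions)  # never its own target

    def test_missing_split_feature_evaluated_at_root(self):
        t = grouped_table(n=2000, sd=1.0, seed=3)
        tree = fit_context_tree(t, "y", min_branch=50)
        f = flag_context(tree, {"grp": None, "y": 50.0})
        assert f is not None
        assert f.conditions == ()

    def test_depth_and_min_branch_respected(self):
        rng = np.random.default_rng(6)
        specs = tuple(ColumnSpec(c, "continuous") for c in "abcy")
        df = pd.DataFrame({c: rng.random(1500) for c in "abcy"})
        t = normalize_table(df, DataDictionary(specs))
        tree = fit_context_tree(t, "y", max_depth=3, min_branch=40)

        def check(node, depth):
            assert node.n >= 40
            if not node.is_leaf:
                assert depth < 3
                check(node.left, depth + 1)
                check(node.right, depth + 1)

        check(tree.root, 0)

    def test_constant_target_gives_empty_tree(self):
        specs = (ColumnSpec("a", "continuous"), ColumnSpec("y", "continuous"))
        df = pd.DataFrame({"a": np.arange(200.0), "y": np.ones(200)})
        t = normalize_table(df, DataDictionary(specs))
        tree = fit_context_tree(t, "y")
        assert tree.root is None
        assert flag_context(tree, {"a": 3.0, "y": 9.0}) is None

    def test_categorical_target_rare_in_dominated_branch_flagged(self):
        rng = np.random.default_rng(7)
        n = 3000
        g = rng.choice(["u", "v"], n)
        y = np.where(g == "u", "red", "blue")
        specs = (ColumnSpec("g", "categorical"), ColumnSpec("y", "categorical"))
        t = normalize_table(pd.DataFrame({"g": g, "y": y}), DataDictionary(specs))
        tree = fit_context_tree(t, "y", min_branch=50)
        f = flag_context(tree, {"g": "u", "y": "blue"})
        assert f is not None and f.flagged

    def test_serialization_round_trip_preserves_decisions(self):
        t = grouped_table(n=1000, sd=1.0, seed=8)
        tree = fit_context_tree(t, "y", min_branch=50)
        tree2 = tree_from_dict(tree_to_dict(tree))
        for row in ({"grp": "g3", "y": 0.0}, {"grp": "g1", "y": 0.2}, {"grp": None, "y": 5.0}):
            a, b = flag_context(tree, row), flag_context(tree2, row)
            assert (a is None) == (b is None)
            if a is not None:
                assert a.flagged == b.flagged and a.conditions == b.conditions
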