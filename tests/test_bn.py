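import numpy as np
import pandas as pd
import pytest

from obsdq.bn import (
    DiscreteBayesNet,
    enumerate_posterior,
    fit_cpts,
    infer,
    learn_structure,
    posterior,
    sample,
    score_cells,
)
from tests.conftest import random_net


def chain_net(p_keep=0.95):
    """A -> B where B copies A with probability p_keep."""
    return DiscreteBayesNet(
        nodes=["A", "B"],
        parents={"A": [], "B": ["A"]},
        states={"A": ["a0", "a1"], "B": ["b0", "b1"]},
        cpts={
            "A": np.array([0.5, 0.5]),
            "B": np.array([[p_keep, 1 - p_keep], [1 - p_keep, p_keep]]),
        },
    )


class TestFitCpts:
    def test_laplace_smoothing_formula(self):
        df = pd.DataFrame({"x": ["a", "a", "a", "b"]})
        net = fit_cpts([], df, alpha=1.0)
        assert net.cpts["x"] == pytest.approx([4 / 6, 2 / 6])

    def test_unseen_parent_configuration_is_uniform(self):
        df = pd.DataFrame({"p": ["u", "u"], "x": ["a", "b"]})
        net = fit_cpts([("p", "x")], df, alpha=1.0,
                       states={"p": ["u", "v"], "x": ["a", "b"]})
        assert net.cpts["x"][1] == pytest.approx([0.5, 0.5])  # parent state v never seen

    def test_alpha_zero_gives_maximum_likelihood(self):
        df = pd.DataFrame({"x": ["a"] * 5})
        net = fit_cpts([], df, alpha=0.0, states={"x": ["a", "b"]})
        assert net.cpts["x"] == pytest.approx([1.0, 0.0])

    def test_cpt_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "a": rng.choice(["x", "y", "z"], 200),
            "b": rng.choice(["u", "v"], 200),
        })
        net = fit_cpts([("a", "b")], df)
        assert np.allclose(net.cpts["b"].sum(axis=-1), 1.0, atol=1e-12)


class TestStructureLearning:
    def test_independent_columns_give_empty_graph(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "a": rng.choice(["0", "1"], 2000),
            "b": rng.choice(["0", "1"], 2000),
        })
        assert learn_structure(df, seed=0) == []

    def test_strong_dependency_gives_exactly_one_edge(self):
        rng = np.random.default_rng(2)
        a = rng.choice(["0", "1"], 2000)
        noise = rng.random(2000) < 0.05
        b = np.where(noise, rng.choice(["0", "1"], 2000), a)
        edges = learn_structure(pd.DataFrame({"a": a, "b": b}), seed=0)
        assert len(edges) == 1
        assert set(edges[0]) == {"a", "b"}

    def test_single_column_errors(self):
        with pytest.raises(ValueError):
            learn_structure(pd.DataFrame({"a": ["0", "1"]}))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({c: rng.choice(["0", "1", "2"], 500) for c in "abcd"})
        assert learn_structure(df, seed=5) == learn_structure(df, seed=5)

    def test_chain_skeleton_recovered(self):
        # data from a 5-node chain; learned skeleton must match
        rng = np.random.default_rng(4)
        n = 5000
        cols = {}
        prev = rng.choice(["0", "1"], n)
        cols["c0"] = prev
        for i in range(1, 5):
            flip = rng.random(n) < 0.12
            prev = np.where(flip, rng.choice(["0", "1"], n), prev)
            cols[f"c{i}"] = prev
        edges = learn_structure(pd.DataFrame(cols), seed=0)
        skeleton = {frozenset(e) for e in edges}
        expected = {frozenset((f"c{i}", f"c{i+1}")) for i in range(4)}
        assert skeleton == expected


class TestInference:
    def test_single_edge_posterior_is_cpt_row(self):
        net = chain_net(0.9)
        post = infer(net, {"A": "a0"}, "B")
        assert post["b0"] == pytest.approx(0.9, abs=1e-12)

    def test_matches_enumeration_on_random_nets(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            net = random_net(rng)
            k = int(rng.integers(0, len(net.nodes)))
            evidence_nodes = list(rng.choice(net.nodes, size=k, replace=False))
            target = next(n for n in net.nodes if n not in evidence_nodes)
            evidence = {n: net.states[n][int(rng.integers(net.card(n)))]
                        for n in evidence_nodes}
            got = infer(net, evidence, target)
            want = enumerate_posterior(net, evidence, target)
            for s in net.states[target]:
                assert got[s] == pytest.approx(want[s], abs=1e-9)

    def test_fast_full_evidence_path_matches_variable_elimination(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            net = random_net(rng)
            target = net.nodes[int(rng.integers(len(net.nodes)))]
            evidence = {n: net.states[n][int(rng.integers(net.card(n)))]
                        for n in net.nodes if n != target}
            fast = posterior(net, evidence, target)
            slow = infer(net, evidence, target)
            for s in net.states[target]:
                assert fast[s] == pytest.approx(slow[s], abs=1e-9)

    def test_unknown_target_errors(self):
        with pytest.raises(KeyError):
            infer(chain_net(), {}, "Z")

    def test_parameter_recovery_from_samples(self):
        net = chain_net(0.8)
        df = sample(net, 8000, seed=1)
        refit = fit_cpts(net.edges(), df, alpha=1.0, states=net.states)
        for node in net.nodes:
            assert refit.cpts[node] == pytest.approx(net.cpts[node], abs=0.03)


class TestScoreCells:
    def test_modal_states_score_one(self):
        net = chain_net(0.95)
        cells, unseen = score_cells(net, {"A": "a0", "B": "b0"})
        assert unseen == []
        assert all(c.normalized_score == 1.0 for c in cells)

    def test_contradicting_deterministic_edge_scores_near_zero(self):
        net = chain_net(0.999)
        cells, _ = score_cells(net, {"A": "a0", "B": "b1"})
        b = next(c for c in cells if c.column == "B")
        assert b.probability < 0.01
        assert b.normalized_score < 0.01

    def test_fully_imputed_row_yields_no_cells(self):
        net = chain_net()
        cells, unseen = score_cells(net, {"A": "a0", "B": "b0"},
                                    {"A": True, "B": True})
        assert cells == [] and unseen == []

    def test_unseen_state_reported_as_conformance_and_dropped(self):
        net = chain_net()
        cells, unseen = score_cells(net, {"A": "a0", "B": "WAT"})
        assert unseen == ["B"]
        assert [c.column for c in cells] == ["A"]

    def test_probability_never_exceeds_mode(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            net = random_net(rng)
            row = {n: net.states[n][int(rng.integers(net.card(n)))] for n in net.nodes}
            cells, _ = score_cells(net, row)
            for c in cells:
                assert c.probability <= c.mode_probability + 1e-12
                assert 0.0 <= c.normalized_score <= 1.0


class TestSampling:
    def test_deterministic_given_seed(self):
        net = chain_net()
        pd.testing.assert_frame_equal(sample(net, 50, seed=3), sample(net, 50, seed=3))

    def test_marginal_frequencies_match(self):
        net = chain_net(0.9)
        df = sample(net, 20000, seed=4)
        agree = (df["A"].str[1] == df["B"].str[1]).mean()
        assert agree == pytest.approx(0.9, abs=0.02)
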