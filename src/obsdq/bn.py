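"""Discrete Bayesian network for contextual plausibility scoring.

The network is learned over the preprocessed (imputed + 3-bin discretized)
columns: greedy hill-climbing on the BIC score with add/remove/reverse moves,
random restarts and a deterministic tie-break, followed by Laplace-smoothed
maximum-likelihood CPT estimation.  At scoring time, the probability of each
registered cell given the rest of the row is computed by exact inference —
variable elimination in general, with a Markov-blanket shortcut when every
other column is observed — and normalized by the posterior-mode probability
so cells of columns with different state counts are comparable.

All factors are dense numpy arrays; the networks here are small (tens of
nodes, <= a handful of states each), so exactness is cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CellPlausibility:
    """Plausibility of one registered cell given the rest of its row."""

    column: str
    registered_state: str
    probability: float  # P(registered | evidence)
    mode_state: str
    mode_probability: float
    normalized_score: float  # probability / mode_probability, in [0,1]


@dataclass
class DiscreteBayesNet:
    nodes: list[str]
    parents: dict[str, list[str]]
    states: dict[str, list[str]]
    cpts: dict[str, np.ndarray]  # shape (*parent cards, node card); rows sum to 1

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges())
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("edge set contains a cycle")
        for n in self.nodes:
            if not self.states[n]:
                raise ValueError(f"empty state space for {n!r}")
            cpt = self.cpts[n]
            if not np.allclose(cpt.sum(axis=-1), 1.0, atol=1e-9):
                raise ValueError(f"CPT rows for {n!r} do not sum to 1")

    def edges(self) -> list[tuple[str, str]]:
        return [(p, c) for c in self.nodes for p in self.parents[c]]

    def card(self, node: str) -> int:
        return len(self.states[node])

    def state_index(self, node: str, state: str) -> int | None:
        try:
            return self.states[node].index(state)
        except ValueError:
            return None

    def topological_order(self) -> list[str]:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges())
        return list(nx.topological_sort(g))

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "version": 1,
            "nodes": list(self.nodes),
            "parents": {n: list(ps) for n, ps in self.parents.items()},
            "states": {n: list(ss) for n, ss in self.states.items()},
            "cpts": {
                n: {"shape": list(self.cpts[n].shape), "probs": self.cpts[n].ravel().tolist()}
                for n in self.nodes
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiscreteBayesNet":
        cpts = {
            n: np.asarray(v["probs"], dtype=float).reshape(v["shape"])
            for n, v in d["cpts"].items()
        }
        return cls(list(d["nodes"]), {k: list(v) for k, v in d["parents"].items()},
                   {k: list(v) for k, v in d["states"].items()}, cpts)


# ---------------------------------------------------------------------------
# encoding and scoring helpers


def _encode(df: pd.DataFrame, states: dict[str, list[str]]) -> dict[str, np.ndarray]:
    codes = {}
    for col, ss in states.items():
        lookup = {s: i for i, s in enumerate(ss)}
        codes[col] = np.asarray([lookup[v] for v in df[col].astype(str)], dtype=np.int64)
    return codes


def _infer_states(df: pd.DataFrame) -> dict[str, list[str]]:
    return {c: sorted(df[c].astype(str).unique().tolist()) for c in df.columns}


def _family_counts(
    node: str, parents: tuple[str, ...], codes: dict[str, np.ndarray],
    cards: dict[str, int],
) -> np.ndarray:
    """Joint counts with shape (*parent cards, node card)."""
    card = cards[node]
    if not parents:
        return np.bincount(codes[node], minlength=card).astype(float)
    pcards = [cards[p] for p in parents]
    cfg = np.ravel_multi_index([codes[p] for p in parents], pcards)
    flat = np.bincount(cfg * card + codes[node], minlength=int(np.prod(pcards)) * card)
    return flat.reshape(*pcards, card).astype(float)


def bic_family_score(
    node: str, parents: tuple[str, ...], codes: dict[str, np.ndarray],
    cards: dict[str, int], n: int,
) -> float:
    """BIC contribution of one node given its parent set (MLE log-likelihood)."""
    counts = _family_counts(node, parents, codes, cards)
    cfg_totals = counts.sum(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(counts > 0, counts * np.log(counts / cfg_totals), 0.0).sum()
    n_params = (cards[node] - 1) * int(np.prod([cards[p] for p in parents], dtype=np.int64))
    return float(ll - 0.5 * math.log(n) * n_params)


def learn_structure(
    train_discrete: pd.DataFrame,
    max_parents: int = 3,
    seed: int = 0,
    restarts: int = 3,
) -> list[tuple[str, str]]:
    """Greedy BIC hill-climb with add/remove/reverse moves and random restarts.

    Deterministic for a fixed seed: candidate moves are scanned in a fixed
    lexicographic order and only a strictly better gain replaces the current
    best, so score ties resolve to the first candidate in that order.
    """
    if hasattr(train_discrete, "df"):
        train_discrete = train_discrete.df
    cols = list(train_discrete.columns)
    if len(cols) < 2:
        raise ValueError("structure learning needs at least 2 columns")
    n = len(train_discrete)
    states = _infer_states(train_discrete)
    cards = {c: len(states[c]) for c in cols}
    codes = _encode(train_discrete, states)

    cache: dict[tuple[str, tuple[str, ...]], float] = {}

    def fam(node: str, parents: tuple[str, ...]) -> float:
        key = (node, tuple(sorted(parents)))
        if key not in cache:
            cache[key] = bic_family_score(node, key[1], codes, cards, n)
        return cache[key]

    def climb(parents: dict[str, list[str]]) -> tuple[dict[str, list[str]], float]:
        g = nx.DiGraph()
        g.add_nodes_from(cols)
        for c, ps in parents.items():
            for p in ps:
                g.add_edge(p, c)
        total = sum(fam(c, tuple(parents[c])) for c in cols)
        while True:
            best_gain, best_move = 1e-9, None
            for u in cols:
                for v in cols:
                    if u == v:
                        continue
                    if g.has_edge(u, v):
                        # remove u -> v
                        new_ps = tuple(p for p in parents[v] if p != u)
                        gain = fam(v, new_ps) - fam(v, tuple(parents[v]))
                        if gain > best_gain:
                            best_gain, best_move = gain, ("remove", u, v)
                        # reverse u -> v
                        if len(parents[u]) < max_parents:
                            g.remove_edge(u, v)
                            ok = not nx.has_path(g, u, v)
                            g.add_edge(u, v)
                            if ok:
                                gain = (
                                    fam(v, new_ps)
                                    - fam(v, tuple(parents[v]))
                                    + fam(u, tuple(parents[u]) + (v,))
                                    - fam(u, tuple(parents[u]))
                                )
                                if gain > best_gain:
                                    best_gain, best_move = gain, ("reverse", u, v)
                    else:
                        # add u -> v
                        if len(parents[v]) >= max_parents:
                            continue
                        if nx.has_path(g, v, u):
                            continue
                        gain = fam(v, tuple(parents[v]) + (u,)) - fam(v, tuple(parents[v]))
                        if gain > best_gain:
                            best_gain, best_move = gain, ("add", u, v)
            if best_move is None:
                return parents, total
            op, u, v = best_move
            if op == "add":
                parents[v] = parents[v] + [u]
                g.add_edge(u, v)
            elif op == "remove":
                parents[v] = [p for p in parents[v] if p != u]
                g.remove_edge(u, v)
            else:  # reverse
                parents[v] = [p for p in parents[v] if p != u]
                parents[u] = parents[u] + [v]
                g.remove_edge(u, v)
                g.add_edge(v, u)
            total += best_gain

    best_parents, best_score = climb({c: [] for c in cols})
    for r in range(1, max(restarts, 1)):
        rng = np.random.default_rng((seed + 7919 * r) % (2**31))
        order = list(rng.permutation(cols))
        start = {c: [] for c in cols}
        g_ok = True
        for j, v in enumerate(order):
            for u in order[:j]:
                if rng.random() < 0.2 and len(start[v]) < max_parents:
                    start[v].append(u)
        parents, score = climb(start)
        if score > best_score + 1e-9:
            best_parents, best_score = parents, score
    return [(p, c) for c in cols for p in sorted(best_parents[c])]


def fit_cpts(
    structure: list[tuple[str, str]],
    train_discrete: pd.DataFrame,
    alpha: float = 1.0,
    states: dict[str, list[str]] | None = None,
) -> DiscreteBayesNet:
    """Laplace-smoothed CPT estimation for a fixed acyclic structure.

    P(x | pa) = (count(x, pa) + alpha) / (count(pa) + alpha * |states(x)|);
    an entirely unseen parent configuration therefore gets the uniform
    distribution.
    """
    if hasattr(train_discrete, "df"):
        train_discrete = train_discrete.df
    cols = list(train_discrete.columns)
    states = states or _infer_states(train_discrete)
    cards = {c: len(states[c]) for c in cols}
    codes = _encode(train_discrete, states)
    parents: dict[str, list[str]] = {c: [] for c in cols}
    for u, v in structure:
        parents[v].append(u)
    cpts = {}
    for node in cols:
        ps = tuple(parents[node])
        counts = _family_counts(node, ps, codes, cards)
        denom = counts.sum(axis=-1, keepdims=True) + alpha * cards[node]
        with np.errstate(divide="ignore", invalid="ignore"):
            cpt = (counts + alpha) / denom
        if alpha == 0.0:
            cpt = np.where(np.isfinite(cpt), cpt, 1.0 / cards[node])
        cpts[node] = cpt
    return DiscreteBayesNet(cols, parents, states, cpts)


# ---------------------------------------------------------------------------
# exact inference


def _reduce_factor(
    variables: list[str], table: np.ndarray, evidence_idx: dict[str, int]
) -> tuple[list[str], np.ndarray]:
    keep_vars, slicer = [], []
    for v in variables:
        if v in evidence_idx:
            slicer.append(evidence_idx[v])
        else:
            keep_vars.append(v)
            slicer.append(slice(None))
    return keep_vars, table[tuple(slicer)]


def _multiply(
    a_vars: list[str], a: np.ndarray, b_vars: list[str], b: np.ndarray
) -> tuple[list[str], np.ndarray]:
    out_vars = list(a_vars) + [v for v in b_vars if v not in a_vars]
    a_shape = [a.shape[a_vars.index(v)] if v in a_vars else 1 for v in out_vars]
    b_shape = [b.shape[b_vars.index(v)] if v in b_vars else 1 for v in out_vars]
    a_r = np.transpose(a, [a_vars.index(v) for v in out_vars if v in a_vars]).reshape(a_shape) \
        if a_vars else a.reshape(a_shape)
    b_r = np.transpose(b, [b_vars.index(v) for v in out_vars if v in b_vars]).reshape(b_shape) \
        if b_vars else b.reshape(b_shape)
    return out_vars, a_r * b_r


def infer(
    net: DiscreteBayesNet, evidence: dict[str, str], target: str
) -> dict[str, float]:
    """Exact posterior P(target | evidence) by variable elimination.

    Unobserved non-target nodes are marginalized out.  Evidence states must
    exist in the node's state space; callers wanting the lenient behavior
    (drop unseen states) should pre-filter, as ``score_cells`` does.
    """
    if target not in net.nodes:
        raise KeyError(f"{target!r} is not a node of the network")
    if target in evidence:
        raise ValueError("target must not appear in the evidence")
    evidence_idx = {}
    for col, state in evidence.items():
        if col not in net.nodes:
            continue
        idx = net.state_index(col, state)
        if idx is None:
            raise ValueError(f"unseen state {state!r} for node {col!r}")
        evidence_idx[col] = idx

    factors: list[tuple[list[str], np.ndarray]] = []
    for node in net.nodes:
        fvars = list(net.parents[node]) + [node]
        keep, tab = _reduce_factor(fvars, net.cpts[node], evidence_idx)
        factors.append((keep, tab))

    hidden = [n for n in net.nodes if n != target and n not in evidence_idx]
    # eliminate smallest-intermediate-factor first (greedy min-size)
    while hidden:
        best_var, best_size = None, None
        for h in hidden:
            vs = set()
            for fv, _ in factors:
                if h in fv:
                    vs.update(fv)
            size = int(np.prod([net.card(v) for v in vs - {h}])) if vs else 1
            if best_size is None or size < best_size or (size == best_size and h < best_var):
                best_var, best_size = h, size
        h = best_var
        involved = [(fv, t) for fv, t in factors if h in fv]
        factors = [(fv, t) for fv, t in factors if h not in fv]
        pv, pt = [], np.array(1.0)
        for fv, t in involved:
            pv, pt = _multiply(pv, pt, fv, t)
        axis = pv.index(h)
        pt = pt.sum(axis=axis)
        pv = [v for v in pv if v != h]
        factors.append((pv, pt))
        hidden.remove(h)

    pv, pt = [], np.array(1.0)
    for fv, t in factors:
        pv, pt = _multiply(pv, pt, fv, t)
    if pv != [target]:
        pt = np.transpose(pt, [pv.index(target)]) if pv else pt
    dist = np.asarray(pt, dtype=float).reshape(net.card(target))
    total = dist.sum()
    if total <= 0:
        dist = np.full(net.card(target), 1.0 / net.card(target))
    else:
        dist = dist / total
    return {s: float(p) for s, p in zip(net.states[target], dist)}


def _posterior_full_evidence(
    net: DiscreteBayesNet, evidence_idx: dict[str, int], target: str
) -> np.ndarray:
    """P(target | all other nodes observed): Markov-blanket product only."""
    card = net.card(target)
    log_unnorm = np.zeros(card)
    # own CPT row
    idx = tuple(evidence_idx[p] for p in net.parents[target])
    log_unnorm += np.log(np.maximum(net.cpts[target][idx], 1e-300))
    # children factors
    for child in net.nodes:
        if target not in net.parents[child]:
            continue
        ps = net.parents[child]
        sel = [slice(None) if p == target else evidence_idx[p] for p in ps]
        col = net.cpts[child][tuple(sel) + (evidence_idx[child],)]
        log_unnorm += np.log(np.maximum(col, 1e-300))
    w = np.exp(log_unnorm - log_unnorm.max())
    return w / w.sum()


def posterior(net: DiscreteBayesNet, evidence: dict[str, str], target: str) -> dict[str, float]:
    """Like :func:`infer` but dispatches to the fast path when possible."""
    known = {c: s for c, s in evidence.items() if c in net.nodes}
    if all(n == target or n in known for n in net.nodes):
        evidence_idx = {}
        for c, s in known.items():
            i = net.state_index(c, s)
            if i is None:
                return infer(net, known, target)  # shouldn't happen; be safe
            evidence_idx[c] = i
        dist = _posterior_full_evidence(net, evidence_idx, target)
        return {s: float(p) for s, p in zip(net.states[target], dist)}
    return infer(net, known, target)


def score_cells(
    net: DiscreteBayesNet,
    row_states: dict[str, str],
    imputed: dict[str, bool] | None = None,
) -> tuple[list[CellPlausibility], list[str]]:
    """Plausibility of every registered (non-imputed) cell given the others.

    Returns ``(cells, conformance_columns)``: cells the network could score,
    and columns whose registered state is absent from the fitted state space
    — those are dropped from all evidence and reported for the conformance
    dimension instead of crashing inference.
    """
    imputed = imputed or {}
    observed: dict[str, str] = {}
    unseen: list[str] = []
    for node in net.nodes:
        if node not in row_states or imputed.get(node, False):
            continue
        state = str(row_states[node])
        if net.state_index(node, state) is None:
            unseen.append(node)
        else:
            observed[node] = state

    cells: list[CellPlausibility] = []
    for node, state in observed.items():
        evidence = {c: s for c, s in observed.items() if c != node}
        dist = posterior(net, evidence, node)
        p = dist[state]
        mode_state = max(dist, key=lambda s: (dist[s], s))
        mode_p = dist[mode_state]
        cells.append(
            CellPlausibility(
                column=node,
                registered_state=state,
                probability=p,
                mode_state=mode_state,
                mode_probability=mode_p,
                normalized_score=1.0 if p >= mode_p - 1e-12 else p / mode_p,
            )
        )
    return cells, unseen


def sample(net: DiscreteBayesNet, n: int, seed: int = 0) -> pd.DataFrame:
    """Ancestral sampling of n rows from the network."""
    rng = np.random.default_rng(seed)
    order = net.topological_order()
    codes: dict[str, np.ndarray] = {}
    for node in order:
        ps = net.parents[node]
        cpt = net.cpts[node]
        if not ps:
            probs = np.broadcast_to(cpt, (n, net.card(node)))
        else:
            idx = tuple(codes[p] for p in ps)
            probs = cpt[idx]
        u = rng.random((n, 1))
        codes[node] = (probs.cumsum(axis=1) > u).argmax(axis=1)
    out = {c: np.asarray(net.states[c], dtype=object)[codes[c]] for c in net.nodes}
    return pd.DataFrame(out, columns=net.nodes)


def enumerate_posterior(
    net: DiscreteBayesNet, evidence: dict[str, str], target: str
) -> dict[str, float]:
    """Brute-force posterior by full joint enumeration (test oracle).

    Exponential in the node count; intended for tiny networks only.
    """
    import itertools

    nodes = net.nodes
    card = net.card(target)
    acc = np.zeros(card)
    spaces = [net.states[nd] for nd in nodes]
    for combo in itertools.product(*spaces):
        assign = dict(zip(nodes, combo))
        if any(assign[c] != s for c, s in evidence.items() if c in assign):
            continue
        p = 1.0
        for nd in nodes:
            idx = tuple(net.states[p_].index(assign[p_]) for p_ in net.parents[nd])
            p *= net.cpts[nd][idx + (net.states[nd].index(assign[nd]),)]
        acc[net.states[target].index(assign[target])] += p
    total = acc.sum()
    if total <= 0:
        acc = np.full(card, 1.0 / card)
    else:
        acc = acc / total
    return {s: float(v) for s, v in zip(net.states[target], acc)}
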