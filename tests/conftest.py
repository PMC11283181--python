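import numpy as np
import pandas as pd
import pytest

from obsdq.engine import QualityEngine
from obsdq.records_io import ColumnSpec, DataDictionary, normalize_table
from obsdq.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def clean_cohort():
    """Moderate clean synthetic cohort shared across tests."""
    return generate_cohort(CohortSpec(n=4000, seed=11))


@pytest.fixture(scope="session")
def engine(clean_cohort):
    """Quality engine fitted once on the shared cohort."""
    return QualityEngine.fit(clean_cohort, seed=0)


@pytest.fixture
def tiny_dictionary():
    return DataDictionary((
        ColumnSpec("pid", "identifier"),
        ColumnSpec("age", "continuous", unit="years"),
        ColumnSpec("n_kids", "count"),
        ColumnSpec("group", "categorical", value_set=("a", "b", "c")),
    ))


def make_table(dictionary, rows):
    """Build a normalized RecordTable from a list of row dicts."""
    df = pd.DataFrame(rows, columns=dictionary.names)
    return normalize_table(df, dictionary)


@pytest.fixture
def make_tiny_table(tiny_dictionary):
    def _make(rows):
        return make_table(tiny_dictionary, rows)

    return _make


def random_net(rng, max_nodes=6, max_states=3):
    """Random small Bayesian network for inference property tests."""
    from obsdq.bn import DiscreteBayesNet

    n_nodes = int(rng.integers(2, max_nodes + 1))
    nodes = [f"v{i}" for i in range(n_nodes)]
    states = {n: [f"s{j}" for j in range(int(rng.integers(2, max_states + 1)))] for n in nodes}
    parents = {n: [] for n in nodes}
    for j in range(n_nodes):
        for i in range(j):
            if rng.random() < 0.4 and len(parents[nodes[j]]) < 3:
                parents[nodes[j]].append(nodes[i])
    cpts = {}
    for n in nodes:
        pcards = [len(states[p]) for p in parents[n]]
        shape = (*pcards, len(states[n]))
        raw = rng.random(shape) + 0.05
        cpts[n] = raw / raw.sum(axis=-1, keepdims=True)
    return DiscreteBayesNet(nodes, parents, states, cpts)
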