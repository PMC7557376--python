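from pathlib import Path

import networkx as nx
import numpy as np
import pytest

from ddsn.io import Action, InteractionRecord, InteractionTable

DATA = Path(__file__).parent / "data"


@pytest.fixture
def data_dir() -> Path:
    return DATA


@pytest.fixture
def worked_example_table() -> InteractionTable:
    """The four-drug / three-target illustration of the projection rule."""
    interactions = {
        "Drug1": {"T1": Action.ANTAGONIST, "T2": Action.AGONIST, "T3": Action.ANTAGONIST},
        "Drug2": {"T1": Action.ANTAGONIST, "T2": Action.AGONIST, "T3": Action.ANTAGONIST},
        "Drug4": {"T1": Action.ANTAGONIST, "T2": Action.AGONIST, "T3": Action.AGONIST},
    }
    records = [
        InteractionRecord(drug_id=d, target_id=t, action=a)
        for d, acts in interactions.items()
        for t, a in acts.items()
    ]
    return InteractionTable(records=records)


@pytest.fixture
def two_triangles() -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from([(1, 2), (2, 3), (1, 3), (4, 5), (5, 6), (4, 6)])
    return g


@pytest.fixture
def bridged_triangles(two_triangles: nx.Graph) -> nx.Graph:
    g = two_triangles.copy()
    g.add_edge(3, 4)
    return g


def random_weighted_graph(rng: np.random.Generator, n_lo=4, n_hi=12, p_lo=0.2, p_hi=0.7):
    n = int(rng.integers(n_lo, n_hi + 1))
    p = float(rng.uniform(p_lo, p_hi))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31 - 1)))
    for u, v in g.edges:
        g[u][v]["weight"] = int(rng.integers(1, 5))
    return g
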