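"""Degree, weighted degree, betweenness, and betweenness/degree (b/d).

Betweenness is computed on the unweighted topology (shortest paths count
hops, not weights) with endpoints excluded and Brandes fractional counting
when a pair has several shortest paths.  Two normalizations are exposed:

* ``mode="pairs"`` divides each node's accumulated path fraction by the
  total number of node pairs C(|V|, 2);
* ``mode="standard"`` uses the conventional normalization by the number of
  pairs that exclude the node itself, C(|V|-1, 2).

Rankings are identical under both; "pairs" is the default because rankings
are what the repurposing prioritization consumes.  b/d divides betweenness
by the unweighted degree, with b/d = 0 for isolated nodes.
"""

from __future__ import annotations

from math import comb
from typing import Hashable

import networkx as nx
import pandas as pd

Node = Hashable


def degree_centralities(g: nx.Graph) -> dict[Node, tuple[int, int]]:
    """Per node: (degree, weighted degree) — edge count and edge-weight sum."""
    return {
        n: (g.degree(n), int(g.degree(n, weight="weight")))
        for n in g.nodes
    }


def betweenness(g: nx.Graph, mode: str = "pairs") -> dict[Node, float]:
    """Normalized betweenness on the unweighted topology, endpoints excluded.

    Pairs in different components contribute 0.  Values lie in [0, 1].
    """
    n = g.number_of_nodes()
    raw = nx.betweenness_centrality(g, normalized=False, weight=None)
    if mode == "pairs":
        denom = comb(n, 2)
    elif mode == "standard":
        denom = comb(n - 1, 2)
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'pairs' or 'standard'")
    if denom == 0:
        return {v: 0.0 for v in raw}
    return {v: b / denom for v, b in raw.items()}


def bd_ratio(
    betw: dict[Node, float], degrees: dict[Node, tuple[int, int]]
) -> dict[Node, float]:
    """b/d per node using the unweighted degree; 0 by convention when d = 0."""
    return {
        v: (betw[v] / degrees[v][0] if degrees[v][0] > 0 else 0.0) for v in betw
    }


def centrality_table(g: nx.Graph, mode: str = "pairs") -> pd.DataFrame:
    """All four centralities as a DataFrame indexed by drug id.

    Columns: degree, weighted_degree, betweenness, bd.
    """
    deg = degree_centralities(g)
    b = betweenness(g, mode=mode)
    bd = bd_ratio(b, deg)
    rows = {
        str(v): {
            "degree": deg[v][0],
            "weighted_degree": deg[v][1],
            "betweenness": b[v],
            "bd": bd[v],
        }
        for v in g.nodes
    }
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "drug_id"
    return df


def binned_distribution(values, bins: int = 8) -> pd.DataFrame:
    """Histogram over linearly spaced bins (plot-ready summary of a centrality)."""
    import numpy as np

    values = np.asarray(list(values), dtype=float)
    counts, edges = np.histogram(values, bins=bins)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
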