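"""Typed bipartite projection of drug-target interactions into the DDSN.

Two drugs are linked iff they act the same way (both agonist or both
antagonist) on at least one shared target; the integer edge weight counts
such targets.  All network statistics downstream are computed on the
largest connected component.
"""

from __future__ import annotations

import itertools
import warnings
from collections import defaultdict

import networkx as nx

from ddsn.io import Action, InteractionTable


def project_ddsn(table: InteractionTable, include_unknown: bool = False) -> nx.Graph:
    """Project a typed interaction table into the weighted drug-drug graph.

    For every unordered drug pair (j, k) the weight is the number of targets
    on which both act with the same known type.  UNKNOWN-action records are
    excluded by default (they cannot match "the same way"); pass
    ``include_unknown=True`` to treat UNKNOWN as a third matchable type.
    Drugs without any edge are kept as isolates, so the projection is a pure
    function of the table.
    """
    records = table.records if include_unknown else table.typed_records()
    if not records:
        warnings.warn("no typed interaction records; projecting an empty graph", stacklevel=2)

    g = nx.Graph()
    names = table.drug_names
    for drug in sorted(table.drugs):
        g.add_node(drug, name=names.get(drug, drug))

    # per target, group interacting drugs by action type; each same-type
    # pair contributes one unit of weight
    by_target: dict[tuple[str, Action], list[str]] = defaultdict(list)
    for rec in records:
        by_target[(rec.target_id, rec.action)].append(rec.drug_id)
    weights: dict[tuple[str, str], int] = defaultdict(int)
    for _, drugs in sorted(by_target.items(), key=lambda kv: (kv[0][0], kv[0][1].value)):
        for a, b in itertools.combinations(sorted(set(drugs)), 2):
            weights[(a, b)] += 1
    for (a, b), w in weights.items():
        g.add_edge(a, b, weight=w)
    return g


def largest_connected_component(g: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest component, weights preserved.

    Size ties break toward the component containing the lexicographically
    smallest node id.  An empty graph maps to an empty graph.
    """
    if g.number_of_nodes() == 0:
        return nx.Graph()
    components = list(nx.connected_components(g))
    largest = max(len(c) for c in components)
    best = min((c for c in components if len(c) == largest), key=lambda c: min(map(str, c)))
    return g.subgraph(best).copy()
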