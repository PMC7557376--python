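"""Modularity, bisection, recursive detection, and community labeling."""

import itertools

import networkx as nx
import numpy as np
import pytest

from ddsn.community import (
    CommunityLabel,
    Partition,
    _modularity_matrix,
    bisect,
    detect_communities,
    label_communities,
    modularity,
)
from ddsn.io import AnnotationTable, Evidence

from conftest import random_weighted_graph


def pairwise_modularity(g: nx.Graph, membership, weighted=True) -> float:
    """Independent oracle: ordered-pair evaluation of the modularity matrix."""
    nodes = sorted(g.nodes, key=str)
    a = nx.to_numpy_array(g, nodelist=nodes, weight="weight" if weighted else None)
    m = a.sum() / 2.0
    if m == 0:
        return 0.0
    k = a.sum(axis=1)
    total = 0.0
    for i, u in enumerate(nodes):
        for j, v in enumerate(nodes):
            if membership[u] == membership[v]:
                total += a[i, j] - k[i] * k[j] / (2 * m)
    return total / (2 * m)


def exhaustive_best_bisection(g: nx.Graph, weighted=True) -> float:
    nodes = sorted(g.nodes, key=str)
    b, w_e = _modularity_matrix(g, nodes, weighted)
    if w_e == 0:
        return 0.0
    n = len(nodes)
    best = 0.0
    for bits in range(2 ** (n - 1)):
        s = np.array([1.0] + [1.0 if (bits >> i) & 1 else -1.0 for i in range(n - 1)])
        best = max(best, float(s @ b @ s) / (4 * w_e))
    return best


class TestModularity:
    def test_single_community_scores_zero(self, two_triangles):
        assert modularity(two_triangles, {n: 1 for n in two_triangles}) == pytest.approx(0.0, abs=1e-15)

    def test_two_triangles_split_scores_half(self, two_triangles):
        p = {1: 1, 2: 1, 3: 1, 4: 2, 5: 2, 6: 2}
        assert modularity(two_triangles, p, weighted=False) == pytest.approx(0.5, abs=1e-12)

    def test_singletons_negative_and_match_oracle(self, two_triangles):
        p = {n: n for n in two_triangles}
        value = modularity(two_triangles, p, weighted=False)
        assert value < 0
        assert value == pytest.approx(pairwise_modularity(two_triangles, p, weighted=False), abs=1e-12)

    def test_weighted_reduces_to_unweighted_on_unit_weights(self, bridged_triangles):
        g = bridged_triangles
        nx.set_edge_attributes(g, 1, "weight")
        p = {1: 1, 2: 1, 3: 1, 4: 2, 5: 2, 6: 2}
        assert modularity(g, p, weighted=True) == pytest.approx(
            modularity(g, p, weighted=False), abs=1e-15
        )

    def test_partition_must_cover_graph(self, two_triangles):
        with pytest.raises(ValueError, match="cover"):
            modularity(two_triangles, {1: 1})

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_pairwise_oracle_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        g = random_weighted_graph(rng, n_lo=3, n_hi=8)
        membership = {n: int(rng.integers(1, 4)) for n in g}
        for weighted in (True, False):
            assert modularity(g, membership, weighted) == pytest.approx(
                pairwise_modularity(g, membership, weighted), abs=1e-12
            )
            assert -1 <= modularity(g, membership, weighted) <= 1


class TestBisect:
    def test_bridged_triangles_split_at_bridge(self, bridged_triangles):
        part, indivisible = bisect(bridged_triangles, weighted=False)
        assert not indivisible
        groups = {frozenset(c) for c in part.communities}
        assert groups == {frozenset({1, 2, 3}), frozenset({4, 5, 6})}

    def test_complete_graph_indivisible(self):
        part, indivisible = bisect(nx.complete_graph(5))
        assert indivisible
        assert part.m == 1

    def test_single_node_indivisible(self):
        part, indivisible = bisect(nx.trivial_graph())
        assert indivisible

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_sign_search(self, seed):
        rng = np.random.default_rng(seed)
        g = random_weighted_graph(rng, n_lo=4, n_hi=10)
        optimum = exhaustive_best_bisection(g)
        part, indivisible = bisect(g)
        achieved = 0.0 if indivisible else modularity(g, part)
        assert achieved == pytest.approx(optimum, abs=1e-9)


class TestDetectCommunities:
    def test_two_triangles_recovered(self, two_triangles):
        part = detect_communities(two_triangles, weighted=False)
        assert part.m == 2
        assert part.modularity == pytest.approx(0.5, abs=1e-12)

    def test_modularity_never_negative(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            g = random_weighted_graph(rng, n_lo=3, n_hi=10)
            part = detect_communities(g)
            assert part.modularity >= -1e-12

    def test_never_beats_exhaustive_partition_optimum(self):
        def all_partitions(nodes):
            if not nodes:
                yield []
                return
            first, rest = nodes[0], nodes[1:]
            for p in all_partitions(rest):
                for i in range(len(p)):
                    yield p[:i] + [[first] + p[i]] + p[i + 1:]
                yield [[first]] + p

        rng = np.random.default_rng(11)
        for _ in range(5):
            g = random_weighted_graph(rng, n_lo=4, n_hi=7)
            best = max(
                modularity(g, {n: i for i, blk in enumerate(p) for n in blk})
                for p in all_partitions(sorted(g.nodes))
            )
            part = detect_communities(g)
            assert part.modularity <= best + 1e-9

    def test_invariant_under_node_relabeling(self):
        rng = np.random.default_rng(23)
        g = random_weighted_graph(rng, n_lo=8, n_hi=8)
        mapping = {n: f"node-{n}" for n in g}
        part1 = detect_communities(g)
        part2 = detect_communities(nx.relabel_nodes(g, mapping))
        groups1 = {frozenset(mapping[n] for n in c) for c in part1.communities}
        groups2 = {frozenset(c) for c in part2.communities}
        assert groups1 == groups2

    def test_greedy_method_agrees_on_easy_graph(self, two_triangles):
        part = detect_communities(two_triangles, method="greedy", seed=0, weighted=False)
        assert part.m == 2
        assert part.modularity == pytest.approx(0.5, abs=1e-12)

    def test_disconnected_graph_handled_per_component(self, two_triangles):
        part = detect_communities(two_triangles)
        assert {frozenset(c) for c in part.communities} == {
            frozenset({1, 2, 3}),
            frozenset({4, 5, 6}),
        }

    def test_unknown_method_rejected(self, two_triangles):
        with pytest.raises(ValueError, match="method"):
            detect_communities(two_triangles, method="simulated_annealing")


class TestLabelCommunities:
    @staticmethod
    def annotations(pairs):
        ann = AnnotationTable()
        for drug, tag in pairs:
            ann.add(drug, tag, Evidence.DATABASE)
        return ann

    def test_majority_tag_dominates(self):
        members = [f"d{i}" for i in range(10)]
        part = Partition({m: 1 for m in members})
        ann = self.annotations([(m, "antifungal") for m in members[:7]])
        (label,) = label_communities(part, ann)
        assert label.dominant_tags == {"antifungal": pytest.approx(0.7)}
        assert label.non_compliant == set(members[7:])

    def test_no_majority_is_unresolved(self):
        part = Partition({"a": 1, "b": 1})
        ann = self.annotations([("a", "x"), ("b", "y")])
        (label,) = label_communities(part, ann)
        assert not label.resolved

    def test_exactly_half_is_not_dominant(self):
        part = Partition({"a": 1, "b": 1, "c": 1, "d": 1})
        ann = self.annotations([("a", "x"), ("b", "x")])
        (label,) = label_communities(part, ann)
        assert not label.resolved
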