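"""Energy model, descent behavior, and layout/modularity agreement."""

import math

import networkx as nx
import numpy as np
import pytest

from ddsn.build import largest_connected_component, project_ddsn
from ddsn.community import Partition, detect_communities
from ddsn.layout import (
    LayoutParams,
    force_layout,
    layout_energy,
    layout_modularity_agreement,
)
from ddsn.synth import SyntheticSpec, generate_interactions


def brute_energy(g, coords, a, r):
    """Independent oracle: direct double loop over unordered pairs."""
    strength = {n: g.degree(n, weight="weight") for n in g}

    def phi(d, e):
        return math.log(d) if abs(e) < 1e-12 else d**e / e

    nodes = sorted(g.nodes, key=str)
    total = 0.0
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            d = math.dist(coords[u], coords[v])
            if g.has_edge(u, v):
                total += g[u][v].get("weight", 1) * phi(d, a + 1)
            total -= strength[u] * strength[v] * phi(d, r + 1)
    return total


@pytest.fixture
def single_edge():
    g = nx.Graph()
    g.add_edge("a", "b", weight=1)
    return g


class TestLayoutEnergy:
    def test_single_edge_hand_value(self, single_edge):
        coords = {"a": (0.0, 0.0), "b": (1.0, 0.0)}
        # attraction 1^2/2 minus repulsion 1*1*1 = -0.5
        assert layout_energy(single_edge, coords) == pytest.approx(-0.5)

    def test_no_edge_pure_repulsion(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=2)
        g.add_edge("c", "d", weight=3)
        coords = {"a": (0, 0), "b": (0, 1), "c": (5, 0), "d": (5, 1)}
        assert layout_energy(g, coords) == pytest.approx(brute_energy(g, coords, 1, 0))

    @pytest.mark.parametrize("a,r", [(1.0, 0.0), (2.0, 0.0), (1.0, -0.5), (0.0, -1.0)])
    def test_matches_brute_oracle(self, a, r):
        rng = np.random.default_rng(4)
        g = nx.gnp_random_graph(8, 0.4, seed=8)
        for u, v in g.edges:
            g[u][v]["weight"] = int(rng.integers(1, 4))
        coords = {n: tuple(rng.normal(size=2)) for n in g}
        params = LayoutParams(a=a, r=r)
        assert layout_energy(g, coords, params) == pytest.approx(
            brute_energy(g, coords, a, r), rel=1e-12
        )

    def test_scaling_homogeneity(self, single_edge):
        # attraction scales as c^(a+1), repulsion as c^(r+1)
        a, r, c = 1.0, -0.5, 3.0
        params = LayoutParams(a=a, r=r)
        d1 = {"a": (0.0, 0.0), "b": (1.0, 0.0)}
        dc = {"a": (0.0, 0.0), "b": (c, 0.0)}
        att1, rep1 = 1 / (a + 1), 1 / (r + 1)
        assert layout_energy(single_edge, d1, params) == pytest.approx(att1 - rep1)
        assert layout_energy(single_edge, dc, params) == pytest.approx(
            c ** (a + 1) * att1 - c ** (r + 1) * rep1
        )

    def test_translation_and_rotation_invariance(self):
        g = nx.cycle_graph(5)
        rng = np.random.default_rng(0)
        coords = {n: tuple(rng.normal(size=2)) for n in g}
        base = layout_energy(g, coords)
        theta = 0.7
        rot = {
            n: (
                x * math.cos(theta) - y * math.sin(theta) + 10.0,
                x * math.sin(theta) + y * math.cos(theta) - 3.0,
            )
            for n, (x, y) in coords.items()
        }
        assert layout_energy(g, rot) == pytest.approx(base, rel=1e-10)

    def test_coincident_nodes_rejected(self, single_edge):
        with pytest.raises(ValueError, match="coincident"):
            layout_energy(single_edge, {"a": (0, 0), "b": (0, 0)})


class TestForceLayout:
    def test_two_node_analytic_equilibrium(self, single_edge):
        # energy d^2/2 - d is minimized at d* = 1
        coords = force_layout(single_edge, LayoutParams(iterations=500, seed=0))
        d = math.dist(coords["a"], coords["b"])
        assert d == pytest.approx(1.0, abs=1e-3)

    @pytest.mark.parametrize("seed", range(4))
    def test_energy_never_increases(self, seed):
        g = nx.gnp_random_graph(12, 0.3, seed=5)
        params = LayoutParams(iterations=50, seed=seed)
        rng = np.random.default_rng(seed)
        init = rng.uniform(-1, 1, size=(len(g), 2)) * math.sqrt(len(g))
        # initial energy from the same seeded start the layout uses
        nodes = sorted(g.nodes, key=str)
        e_init = layout_energy(g, dict(zip(nodes, map(tuple, init))), params)
        coords = force_layout(g, params)
        assert layout_energy(g, coords, params) <= e_init + 1e-9

    def test_deterministic_for_fixed_seed(self, single_edge):
        p = LayoutParams(iterations=50, seed=7)
        assert force_layout(single_edge, p) == force_layout(single_edge, p)

    def test_planted_blocks_are_spatially_separated(self):
        table, truth = generate_interactions(SyntheticSpec(n_drugs=30, n_targets=16, n_blocks=2))
        g = largest_connected_component(project_ddsn(table))
        coords = force_layout(g, LayoutParams(iterations=300, seed=0))
        intra, inter = [], []
        nodes = sorted(g.nodes, key=str)
        for i, u in enumerate(nodes):
            for v in nodes[i + 1:]:
                d = math.dist(coords[u], coords[v])
                (intra if truth.block_of[u] == truth.block_of[v] else inter).append(d)
        assert np.mean(intra) < np.mean(inter)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            force_layout(nx.Graph())


class TestLayoutModularityAgreement:
    def test_perfect_geometric_embedding_gives_nmi_one(self):
        part = Partition({f"n{i}": 1 + i // 5 for i in range(15)})
        coords = {
            f"n{i}": (10.0 * (i // 5) + 0.01 * i, 0.0) for i in range(15)
        }
        assert layout_modularity_agreement(coords, part) == pytest.approx(1.0)

    def test_random_coordinates_give_low_nmi(self):
        rng = np.random.default_rng(0)
        part = Partition({f"n{i}": 1 + i % 4 for i in range(200)})
        coords = {f"n{i}": tuple(rng.uniform(size=2)) for i in range(200)}
        assert layout_modularity_agreement(coords, part, seed=0) < 0.2

    def test_planted_three_blocks_agree(self):
        table, _ = generate_interactions(SyntheticSpec())
        g = largest_connected_component(project_ddsn(table))
        part = detect_communities(g)
        coords = force_layout(g, LayoutParams(iterations=300, seed=0))
        assert layout_modularity_agreement(coords, part, seed=0) >= 0.8

    def test_mismatched_nodes_rejected(self):
        part = Partition({"a": 1})
        with pytest.raises(ValueError, match="same nodes"):
            layout_modularity_agreement({"b": (0, 0)}, part)
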