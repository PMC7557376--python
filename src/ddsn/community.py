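"""Weighted modularity, spectral bisection, and recursive community detection.

Modularity of a partition C_1..C_m of a weighted graph is

    M = sum_i [ w_EC_i / w_E - (w_C_i / (2 w_E))^2 ]

where w_E is the total edge weight, w_EC_i the weight inside community i,
and w_C_i the total weighted degree of its members; with all weights 1 this
reduces to the classic Newman-Girvan form |E_C|/|E| - (d_C / 2|E|)^2.  The
default detector is recursive spectral bisection: split by the leading
eigenvector of the (generalized) modularity matrix, polish with single-node
sign-flip hill climbing, recurse while the overall modularity still
increases.  A greedy multilevel (Louvain) method is offered for parity with
interactive tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

Node = Hashable

#: gains below this are treated as "no improvement" when climbing / recursing
_EPS = 1e-12


@dataclass
class Partition:
    """A disjoint cover of the graph's nodes by communities 1..m."""

    membership: dict[Node, int]
    modularity: float | None = None

    def __post_init__(self) -> None:
        # renumber to consecutive 1..m in first-seen deterministic order
        seen: dict[int, int] = {}
        for node in sorted(self.membership, key=str):
            c = self.membership[node]
            if c not in seen:
                seen[c] = len(seen) + 1
        self.membership = {n: seen[c] for n, c in self.membership.items()}

    @property
    def m(self) -> int:
        return len(set(self.membership.values())) if self.membership else 0

    @property
    def communities(self) -> list[set[Node]]:
        out: dict[int, set[Node]] = {}
        for node, c in self.membership.items():
            out.setdefault(c, set()).add(node)
        return [out[i] for i in sorted(out)]

    def community_of(self, node: Node) -> int:
        return self.membership[node]


@dataclass
class CommunityLabel:
    """Dominant property tag(s) of one community (strict >50% rule)."""

    community: int
    dominant_tags: dict[str, float] = field(default_factory=dict)
    non_compliant: set[Node] = field(default_factory=set)

    @property
    def resolved(self) -> bool:
        return bool(self.dominant_tags)

    @property
    def dominance(self) -> float:
        return max(self.dominant_tags.values(), default=0.0)


def _check_cover(g: nx.Graph, membership: Mapping[Node, int]) -> None:
    if set(membership) != set(g.nodes):
        missing = set(g.nodes) - set(membership)
        extra = set(membership) - set(g.nodes)
        raise ValueError(
            f"partition does not cover the graph exactly "
            f"(missing={sorted(map(str, missing))[:5]}, extra={sorted(map(str, extra))[:5]})"
        )


def _edge_weight(data: dict, weighted: bool) -> float:
    return float(data.get("weight", 1)) if weighted else 1.0


def modularity(
    g: nx.Graph,
    partition: Partition | Mapping[Node, int],
    weighted: bool = True,
) -> float:
    """Community-sum modularity of a partition (weighted by default).

    Computed as sum_C [w_EC/w_E - (w_C/(2 w_E))^2]; the all-in-one partition
    scores exactly 0, and values lie in [-1, 1].
    """
    membership = partition.membership if isinstance(partition, Partition) else dict(partition)
    _check_cover(g, membership)
    w_e = sum(_edge_weight(d, weighted) for _, _, d in g.edges(data=True))
    if w_e == 0:
        return 0.0
    inside: dict[int, float] = {}
    strength: dict[int, float] = {c: 0.0 for c in membership.values()}
    for u, v, data in g.edges(data=True):
        w = _edge_weight(data, weighted)
        if membership[u] == membership[v]:
            inside[membership[u]] = inside.get(membership[u], 0.0) + w
        strength[membership[u]] += w
        strength[membership[v]] += w
    return sum(
        inside.get(c, 0.0) / w_e - (strength[c] / (2.0 * w_e)) ** 2 for c in strength
    )


def _modularity_matrix(
    g: nx.Graph, nodes: Sequence[Node], weighted: bool
) -> tuple[np.ndarray, float]:
    """Dense modularity matrix B = A - k k^T / (2 w_E) over `nodes`, plus w_E."""
    a = nx.to_numpy_array(g, nodelist=nodes, weight="weight" if weighted else None)
    k = a.sum(axis=1)
    w_e = k.sum() / 2.0
    if w_e == 0:
        return np.zeros_like(a), 0.0
    return a - np.outer(k, k) / (2.0 * w_e), w_e


def _generalized_b(b_full: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Newman's B^(C) for subdividing community C: restrict and fix the diagonal."""
    sub = b_full[np.ix_(idx, idx)].copy()
    sub[np.diag_indices_from(sub)] -= sub.sum(axis=1)
    return sub


def _climb(b: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Kernighan-Lin-style single-flip polishing of s^T B s (deterministic).

    Each pass flips every node exactly once, always taking the currently
    best flip (even when its immediate gain is negative), then rewinds to
    the best state seen during the pass; passes repeat while they improve.
    This escapes the single-flip local optima that plain steepest ascent
    gets stuck in.
    """
    n = s.size
    diag = np.diag(b).copy()
    best_val = float(s @ b @ s)
    while True:
        cur = s.copy()
        bs = b @ cur
        cur_val = best_val
        moved = np.zeros(n, dtype=bool)
        pass_best_val = best_val
        pass_best = s.copy()
        for _ in range(n):
            gains = -4.0 * cur * bs + 4.0 * diag
            gains[moved] = -np.inf
            i = int(np.argmax(gains))  # first max wins: node-order tie-break
            cur[i] = -cur[i]
            moved[i] = True
            bs += 2.0 * cur[i] * b[:, i]
            cur_val += float(gains[i])
            if cur_val > pass_best_val + _EPS * max(1.0, abs(pass_best_val)):
                pass_best_val = cur_val
                pass_best = cur.copy()
        if pass_best_val > best_val + _EPS * max(1.0, abs(best_val)):
            s, best_val = pass_best, pass_best_val
        else:
            return s


def _spectral_split(b: np.ndarray, w_e: float, n_restarts: int = 8) -> tuple[np.ndarray, float]:
    """Best two-way split of the (generalized) modularity matrix.

    Polishes several deterministic starts — sign and median splits of the
    top two eigenvectors plus a fixed-seed batch of random sign vectors —
    with Kernighan-Lin climbing and keeps the best.  Returns
    (signs, delta_M); delta_M <= 0 signals an indivisible group.
    """
    n = b.shape[0]
    if n < 2 or w_e <= 0:
        return np.ones(n), 0.0
    sym = (b + b.T) / 2.0
    _, vecs = np.linalg.eigh(sym)
    starts = []
    for k in (1, 2):
        if k > n:
            break
        v = vecs[:, -k]
        nz = np.nonzero(np.abs(v) > 1e-15)[0]
        if nz.size and v[nz[0]] < 0:  # deterministic sign convention
            v = -v
        starts.append(np.where(v >= 0, 1.0, -1.0))
        starts.append(np.where(v >= np.median(v), 1.0, -1.0))
    rng = np.random.default_rng(12345)  # fixed: bisect is deterministic
    for _ in range(n_restarts):
        starts.append(np.where(rng.random(n) < 0.5, 1.0, -1.0))
    best_s, best_val = np.ones(n), 0.0
    for s0 in starts:
        s = _climb(b, s0.copy())
        if np.all(s == s[0]):
            continue
        val = float(s @ b @ s)
        if val > best_val:
            best_val, best_s = val, s
    delta = best_val / (4.0 * w_e)
    if delta <= 0 or np.all(best_s == best_s[0]):
        return np.ones(n), 0.0
    return best_s, delta


def bisect(g: nx.Graph, weighted: bool = True) -> tuple[Partition, bool]:
    """Best two-way split of `g` by maximum modularity.

    Returns ``(partition, indivisible)``: when no split improves on the
    trivial single community the trivial partition is returned with
    ``indivisible=True``.
    """
    nodes = sorted(g.nodes, key=str)
    if len(nodes) < 2:
        return Partition({n: 1 for n in nodes}, modularity=0.0), True
    b, w_e = _modularity_matrix(g, nodes, weighted)
    s, delta = _spectral_split(b, w_e)
    if delta <= _EPS:
        return Partition({n: 1 for n in nodes}, modularity=0.0), True
    membership = {n: (1 if si > 0 else 2) for n, si in zip(nodes, s)}
    return Partition(membership, modularity=modularity(g, membership, weighted)), False


def detect_communities(
    g: nx.Graph,
    method: str = "recursive_bisection",
    seed: int = 0,
    weighted: bool = True,
) -> Partition:
    """Detect communities by recursive bisection (default) or greedy Louvain.

    Recursive bisection repeatedly splits each community with the
    generalized modularity-change criterion and stops when no split
    increases the overall modularity; disconnected graphs are handled per
    component.  ``method="greedy"`` delegates to a weighted multilevel merge
    ascent (Louvain).  Deterministic for a fixed seed.
    """
    if g.number_of_nodes() == 0:
        return Partition({}, modularity=0.0)
    if method == "greedy":
        comms = nx.community.louvain_communities(
            g, weight="weight" if weighted else None, seed=seed
        )
        membership = {n: i + 1 for i, c in enumerate(sorted(map(sorted, comms))) for n in c}
        return Partition(membership, modularity=modularity(g, membership, weighted))
    if method != "recursive_bisection":
        raise ValueError(f"unknown method {method!r}")

    nodes = sorted(g.nodes, key=str)
    index = {n: i for i, n in enumerate(nodes)}
    b_full, w_e = _modularity_matrix(g, nodes, weighted)

    final: list[list[Node]] = []
    # seed groups: connected components (recursion needs connected pieces)
    stack = [sorted(c, key=str) for c in nx.connected_components(g)]
    stack.sort(key=lambda c: str(c[0]))
    while stack:
        group = stack.pop()
        if len(group) < 2 or w_e <= 0:
            final.append(group)
            continue
        idx = np.array([index[n] for n in group])
        b_sub = _generalized_b(b_full, idx)
        s, delta = _spectral_split(b_sub, w_e)
        if delta <= _EPS:
            final.append(group)
            continue
        left = [n for n, si in zip(group, s) if si > 0]
        right = [n for n, si in zip(group, s) if si <= 0]
        stack.extend([left, right])
    final.sort(key=lambda c: str(min(map(str, c))))
    membership = {n: i + 1 for i, c in enumerate(final) for n in c}
    return Partition(membership, modularity=modularity(g, membership, weighted))


def label_communities(
    partition: Partition,
    annotations,
    threshold: float = 0.5,
) -> list[CommunityLabel]:
    """Label each community by property tags held by a strict majority.

    A tag is dominant when its frequency among members strictly exceeds
    ``threshold`` (default 0.5).  Members lacking every dominant tag form
    the non-compliant set — the community's repurposing candidates.
    Communities with no dominant tag are left UNRESOLVED (no tags).
    """
    labels = []
    for i, members in enumerate(partition.communities, start=1):
        counts: dict[str, int] = {}
        for node in members:
            for tag in annotations.tags_of(node):
                counts[tag] = counts.get(tag, 0) + 1
        size = len(members)
        dominant = {t: c / size for t, c in counts.items() if c / size > threshold}
        non_compliant = {
            node for node in members if not (annotations.tags_of(node) & set(dominant))
        } if dominant else set()
        labels.append(CommunityLabel(community=i, dominant_tags=dominant, non_compliant=non_compliant))
    return labels
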