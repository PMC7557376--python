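"""Noack-family energy-model force-directed layout and its cluster agreement.

The layout minimizes, over 2D node coordinates, the energy

    E = sum_{(i,j) in E} w_ij * d_ij^(a+1) / (a+1)
      - sum_{i<j}        w_i w_j * d_ij^(r+1) / (r+1)

with attraction exponent a >= 0 acting on adjacent pairs and repulsion
exponent r <= 0 acting on all distinct pairs; w_i is the weighted degree of
node i and exponent 0 in the denominator is replaced by the logarithmic
limit (d^p/p -> ln d as p -> 0).  Within Noack's admissible region
(a > -1, r > -1) the spatial clusters of a minimal-energy layout coincide
with the graph's modularity communities, which
:func:`layout_modularity_agreement` quantifies via k-means + NMI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Mapping

import networkx as nx
import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import normalized_mutual_info_score

Node = Hashable


@dataclass
class LayoutParams:
    """Exponents and descent controls for the energy layout.

    The default (a=1, r=0) gives quadratic attraction energy and linear
    repulsion energy; (a, r) = (1, -1) is the LinLog-style variant whose
    repulsion energy is the logarithmic limit of d^(r+1)/(r+1).
    """

    a: float = 1.0
    r: float = 0.0
    iterations: int = 1000
    step: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.a >= 0 and -1 <= self.r <= 0):
            raise ValueError("require a >= 0 and -1 <= r <= 0")


def _phi(dist: np.ndarray, exponent: float) -> np.ndarray:
    """d^p / p with the p -> 0 logarithmic limit (p = exponent here)."""
    if abs(exponent) < 1e-12:
        return np.log(dist)
    return dist**exponent / exponent


def _as_arrays(g: nx.Graph) -> tuple[list[Node], np.ndarray, np.ndarray]:
    nodes = sorted(g.nodes, key=str)
    adj = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    strength = adj.sum(axis=1)
    return nodes, adj, strength


def layout_energy(
    g: nx.Graph,
    coords: Mapping[Node, tuple[float, float]],
    params: LayoutParams | None = None,
) -> float:
    """Energy of a concrete embedding (lower = tighter clusters)."""
    params = params or LayoutParams()
    nodes, adj, strength = _as_arrays(g)
    pos = np.array([coords[n] for n in nodes], dtype=float)
    if not np.all(np.isfinite(pos)):
        raise ValueError("coordinates must be finite")
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    iu = np.triu_indices(len(nodes), k=1)
    d = dist[iu]
    if np.any(d <= 0):
        raise ValueError("coincident nodes; jitter the layout first")
    attraction = float((adj[iu] * _phi(d, params.a + 1.0))[adj[iu] > 0].sum())
    rep_w = np.outer(strength, strength)[iu]
    repulsion = float((rep_w * _phi(d, params.r + 1.0)).sum())
    return attraction - repulsion


def _gradient(
    pos: np.ndarray, adj: np.ndarray, strength: np.ndarray, params: LayoutParams
) -> np.ndarray:
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    np.fill_diagonal(dist, 1.0)  # diagonal never used
    # d/dpos_i of d^p/p is d^(p-2) * (pos_i - pos_j) for p != 0, and the
    # same expression with p = 0 for the logarithmic limit
    att = adj * dist ** (params.a - 1.0)
    rep = np.outer(strength, strength) * dist ** (params.r - 1.0)
    np.fill_diagonal(att, 0.0)
    np.fill_diagonal(rep, 0.0)
    coef = att - rep
    return (coef[:, :, None] * diff).sum(axis=1)


def force_layout(g: nx.Graph, params: LayoutParams | None = None) -> dict[Node, tuple[float, float]]:
    """Gradient descent on the layout energy from seeded random coordinates.

    Adaptive step size (backtracking on energy increase) guarantees the
    returned energy never exceeds the initial one; coincident points are
    jittered apart.  Deterministic for a fixed seed.
    """
    params = params or LayoutParams()
    if g.number_of_nodes() == 0:
        raise ValueError("cannot lay out an empty graph")
    nodes, adj, strength = _as_arrays(g)
    n = len(nodes)
    rng = np.random.default_rng(params.seed)
    pos = rng.uniform(-1.0, 1.0, size=(n, 2)) * max(1.0, np.sqrt(n))

    def jitter(p: np.ndarray) -> np.ndarray:
        diff = p[:, None, :] - p[None, :, :]
        dist = np.sqrt((diff**2).sum(-1))
        np.fill_diagonal(dist, np.inf)
        while dist.min() < 1e-9:
            i, j = np.unravel_index(int(np.argmin(dist)), dist.shape)
            p[i] += rng.normal(scale=1e-6, size=2)
            diff = p[:, None, :] - p[None, :, :]
            dist = np.sqrt((diff**2).sum(-1))
            np.fill_diagonal(dist, np.inf)
        return p

    pos = jitter(pos)

    def energy(p: np.ndarray) -> float:
        return layout_energy(g, {nd: tuple(xy) for nd, xy in zip(nodes, p)}, params)

    e = energy(pos)
    step = params.step
    for _ in range(params.iterations):
        grad = _gradient(pos, adj, strength, params)
        norm = np.sqrt((grad**2).sum(axis=1)).max()
        if norm < 1e-14:
            break
        trial = jitter(pos - step * grad / norm)
        e_trial = energy(trial)
        if e_trial < e:
            pos, e = trial, e_trial
            step *= 1.2
        else:
            step *= 0.5
            if step < 1e-12:
                break
    return {nd: (float(x), float(y)) for nd, (x, y) in zip(nodes, pos)}


def layout_modularity_agreement(
    coords: Mapping[Node, tuple[float, float]],
    partition,
    k: int | None = None,
    seed: int = 0,
    n_restarts: int = 10,
) -> float:
    """NMI between geometric k-means clusters of a layout and a partition.

    k defaults to the partition's community count; k-means uses the best of
    ``n_restarts`` seeded restarts.  Returns a value in [0, 1]; 1 means the
    spatial clusters reproduce the modularity communities exactly.
    """
    nodes = sorted(coords, key=str)
    if set(nodes) != set(partition.membership):
        raise ValueError("coords and partition must cover the same nodes")
    k = k or partition.m
    x = np.array([coords[n] for n in nodes])
    geo = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit_predict(x)
    ref = [partition.membership[n] for n in nodes]
    return float(normalized_mutual_info_score(ref, geo))
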