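"""Bundled and synthetic weighted networks used in examples and tests.

The canonical fixture is the Les Misérables character co-occurrence network
(77 nodes, 254 edges): nodes are characters of Victor Hugo's novel, an edge
connects characters appearing in the same chapter, and the weight counts
those co-occurrences.  Synthetic generators produce small named topologies
and seeded random weighted graphs; the same spec and seed always yield a
bit-identical graph.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from .graphio import as_weighted_network

__all__ = [
    "les_miserables",
    "star",
    "path",
    "triangle",
    "two_cliques_bridge",
    "random_weighted",
]


def les_miserables() -> nx.Graph:
    """The weighted Les Misérables co-occurrence network (N=77, E=254)."""
    return as_weighted_network(nx.les_miserables_graph())


def star(n: int, weights=None) -> nx.Graph:
    """Star with a center ``"c"`` and ``n`` leaves ``"v1" .. "vn"``."""
    if n < 1:
        raise ValueError("star needs at least one leaf")
    if weights is None:
        weights = [1.0] * n
    if len(weights) != n:
        raise ValueError("need one weight per leaf")
    g = nx.Graph()
    for i, w in enumerate(weights, start=1):
        g.add_edge("c", f"v{i}", weight=float(w))
    return as_weighted_network(g)


def path(n: int, weights=None) -> nx.Graph:
    """Path on ``n`` nodes ``"v1" .. "vn"`` (n-1 edges)."""
    if n < 2:
        raise ValueError("path needs at least two nodes")
    if weights is None:
        weights = [1.0] * (n - 1)
    if len(weights) != n - 1:
        raise ValueError("need n-1 weights")
    g = nx.Graph()
    for i, w in enumerate(weights, start=1):
        g.add_edge(f"v{i}", f"v{i + 1}", weight=float(w))
    return as_weighted_network(g)


def triangle(w1: float = 1.0, w2: float = 1.0, w3: float = 1.0) -> nx.Graph:
    """Triangle on ``a,b,c`` with weights (a-b)=w1, (b-c)=w2, (a-c)=w3."""
    g = nx.Graph()
    g.add_edge("a", "b", weight=float(w1))
    g.add_edge("b", "c", weight=float(w2))
    g.add_edge("a", "c", weight=float(w3))
    return as_weighted_network(g)


def two_cliques_bridge(k: int, clique_weight: float = 1.0, bridge_weight: float = 1.0) -> nx.Graph:
    """Two k-cliques joined by a single bridge edge.

    Nodes ``"a1..ak"`` and ``"b1..bk"``; the bridge connects ``"a1"``-``"b1"``.
    """
    if k < 2:
        raise ValueError("cliques need at least two nodes")
    g = nx.Graph()
    for prefix in ("a", "b"):
        for i in range(1, k + 1):
            for j in range(i + 1, k + 1):
                g.add_edge(f"{prefix}{i}", f"{prefix}{j}", weight=float(clique_weight))
    g.add_edge("a1", "b1", weight=float(bridge_weight))
    return as_weighted_network(g)


def random_weighted(
    n: int,
    p_edge: float,
    weight_dist: str = "uniform",
    seed: int | None = 0,
    *,
    distinct: bool = False,
    connected: bool = False,
) -> nx.Graph:
    """Seeded Erdős–Rényi graph with random positive weights.

    Parameters
    ----------
    n, p_edge
        Number of nodes and edge probability.
    weight_dist
        ``"uniform"`` (on (0.5, 10.5)), ``"lognormal"`` (μ=1, σ=1) or
        ``"integer"`` (uniform on 1..20, for count-based null models).
    distinct
        Guarantee pairwise-distinct weights (required by distance-backbone
        uniqueness properties); implemented by rank-separated jitter.
    connected
        Add a random spanning chain first so the graph is connected.
    """
    if n < 1:
        raise ValueError("n must be positive")
    if not 0 <= p_edge <= 1:
        raise ValueError("p_edge must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    nodes = [f"v{i}" for i in range(1, n + 1)]
    g = nx.Graph()
    g.add_nodes_from(nodes)
    if connected and n > 1:
        order = rng.permutation(n)
        for a, b in zip(order, order[1:]):
            g.add_edge(nodes[a], nodes[b])
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                g.add_edge(nodes[i], nodes[j])
    m = g.number_of_edges()
    if weight_dist == "uniform":
        w = rng.uniform(0.5, 10.5, size=m)
    elif weight_dist == "lognormal":
        w = rng.lognormal(mean=1.0, sigma=1.0, size=m)
    elif weight_dist == "integer":
        w = rng.integers(1, 21, size=m).astype(float)
    else:
        raise ValueError(f"unknown weight_dist {weight_dist!r}")
    if distinct and m:
        # rank-proportional jitter: ties become distinct, ordering is kept and
        # the offsets stay far below the smallest possible nonzero gap
        rank = np.argsort(np.argsort(w, kind="stable"), kind="stable")
        w = w * (1.0 + 1e-9 * rank) + 1e-9 * rank
        assert len(np.unique(w)) == m
    for (u, v), wi in zip(g.edges(), w):
        g[u][v]["weight"] = float(wi)
    return as_weighted_network(g)
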