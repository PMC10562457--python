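"""Structural backbone methods.

Score-based methods annotate edges (or nodes) with a topological score that
threshold/fraction filters can cut; substructure methods (spanning tree,
distance backbones, PMFG, ...) attach a boolean membership flag.

Path-based scores interpret weights as proximities and travel on reciprocal
distances d = 1/w by default (strong edges are short); the map is
configurable wherever it matters.
"""

from __future__ import annotations

import math
from typing import Callable

import networkx as nx
import numpy as np

from .backbone import FILTER_COMPATIBILITY, BackboneResult

__all__ = [
    "global_threshold",
    "maximum_spanning_tree",
    "doubly_stochastic",
    "high_salience_skeleton",
    "h_backbone",
    "metric_backbone",
    "ultrametric_backbone",
    "modularity_vitality",
    "pmfg",
    "primary_linkage",
    "jaccard_sparsification",
    "edge_betweenness",
    "node_degree",
]

RECIPROCAL: Callable[[float], float] = lambda w: 1.0 / w  # noqa: E731


def _with_distances(net: nx.Graph, distance: Callable[[float], float]) -> nx.Graph:
    g = net.copy()
    for u, v, d in g.edges(data=True):
        dist = float(distance(d["weight"]))
        if dist <= 0 or not math.isfinite(dist):
            raise ValueError(f"distance map produced {dist} for weight {d['weight']}")
        d["distance"] = dist
    return g


def _edge_key(u, v):
    return (u, v) if u <= v else (v, u)


def _result(g, name, prop, *, boolean=None, filter_on="edges"):
    return BackboneResult(
        graph=g,
        method_name=name,
        property_name=prop,
        is_pvalue=False,
        compatible_filters=FILTER_COMPATIBILITY[name],
        filter_on=filter_on,
        boolean_attribute=boolean,
    )


# ---------------------------------------------------------------------------
# weight-rank methods
# ---------------------------------------------------------------------------

def global_threshold(net: nx.Graph) -> BackboneResult:
    """Raw edge weight as the score; cut with a threshold β or a fraction."""
    g = net.copy()
    for _, _, d in g.edges(data=True):
        d["score"] = float(d["weight"])
    return _result(g, "Global Threshold Filter", "score")


def maximum_spanning_tree(net: nx.Graph) -> BackboneResult:
    """Maximum-weight spanning tree (forest on disconnected input).

    Kruskal with a deterministic tie-break: weight descending, then
    lexicographic edge identifier.
    """
    g = net.copy()
    subtrees = nx.utils.UnionFind(g.nodes)
    edges = sorted(
        g.edges(data=True), key=lambda e: (-e[2]["weight"], _edge_key(e[0], e[1]))
    )
    member: set = set()
    for u, v, d in edges:
        if subtrees[u] != subtrees[v]:
            member.add(frozenset((u, v)))
            subtrees.union(u, v)
    for u, v, d in g.edges(data=True):
        d["in_backbone"] = frozenset((u, v)) in member
    return _result(g, "Maximum Spanning Tree", "in_backbone", boolean="in_backbone")


def primary_linkage(net: nx.Graph) -> BackboneResult:
    """Keep, for every node, its single maximum-weight incident edge."""
    g = net.copy()
    keep: set = set()
    for node in g.nodes:
        nbrs = list(g[node])
        if not nbrs:
            continue
        best = min(nbrs, key=lambda x: (-g[node][x]["weight"], x))
        keep.add(frozenset((node, best)))
    for u, v, d in g.edges(data=True):
        d["in_backbone"] = frozenset((u, v)) in keep
    return _result(g, "Primary Linkage Analysis", "in_backbone", boolean="in_backbone")


# ---------------------------------------------------------------------------
# doubly stochastic filter
# ---------------------------------------------------------------------------

def doubly_stochastic(
    net: nx.Graph, tol: float = 1e-6, max_sweeps: int = 1000
) -> BackboneResult:
    """Sinkhorn scaling of the weight matrix to doubly stochastic form.

    The converged entries are the edge scores.  The native boolean rule adds
    edges in descending score order until the backbone connects all nodes in
    a single component (or edges run out on disconnected input).  Raises if
    row/column sums have not converged to 1 within ``max_sweeps``.
    """
    if net.number_of_edges() == 0:
        raise ValueError("graph has no edges")
    nodes = [n for n in net.nodes if net.degree(n) > 0]
    idx = {n: i for i, n in enumerate(nodes)}
    a = np.zeros((len(nodes), len(nodes)))
    for u, v, d in net.edges(data=True):
        a[idx[u], idx[v]] = a[idx[v], idx[u]] = d["weight"]
    m = a.copy()
    for _ in range(max_sweeps):
        m = m / m.sum(axis=1, keepdims=True)
        m = m / m.sum(axis=0, keepdims=True)
        if (
            np.abs(m.sum(axis=1) - 1.0).max() < tol
            and np.abs(m.sum(axis=0) - 1.0).max() < tol
        ):
            break
    else:
        raise RuntimeError(
            f"doubly stochastic scaling did not converge within {max_sweeps} sweeps "
            "(the matrix may admit no doubly stochastic form)"
        )
    m = (m + m.T) / 2.0
    g = net.copy()
    for u, v, d in g.edges(data=True):
        d["score"] = float(m[idx[u], idx[v]])
    # native boolean rule: connect everything with the highest scores
    order = sorted(
        g.edges(data=True), key=lambda e: (-e[2]["score"], _edge_key(e[0], e[1]))
    )
    bb = nx.Graph()
    bb.add_nodes_from(net.nodes)
    member: set = set()
    for u, v, d in order:
        if nx.is_connected(bb):
            break
        bb.add_edge(u, v)
        member.add(frozenset((u, v)))
    for u, v, d in g.edges(data=True):
        d["in_backbone"] = frozenset((u, v)) in member
    return _result(g, "Doubly Stochastic Filter", "score", boolean="in_backbone")


# ---------------------------------------------------------------------------
# high salience skeleton
# ---------------------------------------------------------------------------

def salience(net: nx.Graph, distance: Callable[[float], float] = RECIPROCAL) -> dict:
    """Per-edge salience: the fraction of per-root shortest-path trees that
    contain the edge.

    For each root the tree is the union of one shortest path to every other
    node, the path found first by Dijkstra (ties resolved in adjacency
    discovery order, deterministic for a fixed input graph).
    """
    g = _with_distances(net, distance)
    n = g.number_of_nodes()
    count = {_edge_key(u, v): 0 for u, v in g.edges}
    for root in g.nodes:
        paths = nx.single_source_dijkstra_path(g, root, weight="distance")
        tree = set()
        for target, p in paths.items():
            for a, b in zip(p, p[1:]):
                tree.add(_edge_key(a, b))
        for e in tree:
            count[e] += 1
    return {e: c / n for e, c in count.items()}


def high_salience_skeleton(
    net: nx.Graph,
    distance: Callable[[float], float] = RECIPROCAL,
    boolean_threshold: float = 0.8,
) -> BackboneResult:
    """High salience skeleton: salience scores with the native rule s > 0.8.

    Salience is bimodal (most edges sit near 0 or 1), so the default boolean
    rule keeps edges appearing in more than 80% of the shortest-path trees.
    """
    if net.number_of_edges() == 0:
        raise ValueError("graph has no edges")
    g = net.copy()
    sal = salience(net, distance)
    for u, v, d in g.edges(data=True):
        s = sal[_edge_key(u, v)]
        d["score"] = s
        d["in_backbone"] = s > boolean_threshold
    return _result(g, "High Salience Skeleton", "score", boolean="in_backbone")


# ---------------------------------------------------------------------------
# h-backbone
# ---------------------------------------------------------------------------

def _hirsch(values) -> int:
    """Largest natural number h such that at least h values are >= h."""
    vals = sorted(values, reverse=True)
    h = 0
    for i, v in enumerate(vals, start=1):
        if v >= i:
            h = i
        else:
            break
    return h


def h_backbone(net: nx.Graph, distance: Callable[[float], float] = RECIPROCAL) -> BackboneResult:
    """h-backbone: union of the h-strength and h-bridge networks.

    h-strength: Hirsch rule on raw weights (largest h with h edges of weight
    ≥ h); h-bridge: the same rule on bridge values, i.e. weighted edge
    betweenness (reciprocal distances, raw pair counts) divided by the number
    of nodes.  An h of zero contributes no edges.
    """
    if net.number_of_edges() == 0:
        raise ValueError("graph has no edges")
    g = _with_distances(net, distance)
    n = g.number_of_nodes()
    weights = {_edge_key(u, v): d["weight"] for u, v, d in g.edges(data=True)}
    h_s = _hirsch(weights.values())
    strength_set = {e for e, w in weights.items() if h_s > 0 and w >= h_s}
    betw = nx.edge_betweenness_centrality(g, weight="distance", normalized=False)
    bridge = {_edge_key(u, v): b / n for (u, v), b in betw.items()}
    h_b = _hirsch(bridge.values())
    bridge_set = {e for e, b in bridge.items() if h_b > 0 and b >= h_b}
    member = strength_set | bridge_set
    out = net.copy()
    for u, v, d in out.edges(data=True):
        d["in_backbone"] = _edge_key(u, v) in member
        d["bridge"] = bridge[_edge_key(u, v)]
    return _result(out, "h-Backbone", "in_backbone", boolean="in_backbone")


# ---------------------------------------------------------------------------
# metric and ultrametric distance backbones
# ---------------------------------------------------------------------------

def metric_backbone(
    net: nx.Graph, distance: Callable[[float], float] = RECIPROCAL
) -> BackboneResult:
    """Keep edges whose direct distance is no longer than any indirect path,
    with path length the **sum** of edge distances.

    Equivalently: the edge (i, j) survives iff d_ij equals the shortest-path
    distance between i and j.
    """
    g = _with_distances(net, distance)
    member = set()
    for root in g.nodes:
        dist = nx.single_source_dijkstra_path_length(g, root, weight="distance")
        for nbr in g[root]:
            d_direct = g[root][nbr]["distance"]
            if d_direct <= dist[nbr] * (1.0 + 1e-12):
                member.add(_edge_key(root, nbr))
    out = net.copy()
    for u, v, d in out.edges(data=True):
        d["in_backbone"] = _edge_key(u, v) in member
    return _result(out, "Metric Backbone", "in_backbone", boolean="in_backbone")


def ultrametric_backbone(
    net: nx.Graph, distance: Callable[[float], float] = RECIPROCAL
) -> BackboneResult:
    """Keep edges consistent with minimax paths: path length is the
    **maximum** edge distance along the path.

    The minimax distance between two nodes equals the largest edge distance
    on their path through a minimum-distance spanning forest, so the test
    runs on that forest.  The output is invariant to the choice of monotone
    weight→distance map.
    """
    g = _with_distances(net, distance)
    forest = nx.minimum_spanning_tree(g, weight="distance")
    # largest forest-path edge distance from each root, by tree traversal
    member = set()
    for root in g.nodes:
        maxd = {root: 0.0}
        stack = [root]
        while stack:
            cur = stack.pop()
            for nbr in forest[cur]:
                if nbr not in maxd:
                    maxd[nbr] = max(maxd[cur], forest[cur][nbr]["distance"])
                    stack.append(nbr)
        for nbr in g[root]:
            d_direct = g[root][nbr]["distance"]
            if nbr in maxd and d_direct <= maxd[nbr] * (1.0 + 1e-12):
                member.add(_edge_key(root, nbr))
    out = net.copy()
    for u, v, d in out.edges(data=True):
        d["in_backbone"] = _edge_key(u, v) in member
    return _result(out, "Ultrametric Backbone", "in_backbone", boolean="in_backbone")


# ---------------------------------------------------------------------------
# modularity backbone (node vitality)
# ---------------------------------------------------------------------------

def modularity_vitality(net: nx.Graph, seed: int = 42) -> BackboneResult:
    """Node score: |ΔQ| caused by removing the node.

    A partition is detected once on the full graph (Louvain, fixed seed);
    each node's vitality is the absolute change in weighted modularity
    between the full graph and the graph without the node, evaluating the
    same partition restricted to the remaining nodes.
    """
    if net.number_of_nodes() < 2:
        raise ValueError("modularity vitality needs at least two nodes")
    g = net.copy()
    communities = nx.community.louvain_communities(g, weight="weight", seed=seed)
    q_full = nx.community.modularity(g, communities, weight="weight")
    for node in g.nodes:
        rest = g.copy()
        rest.remove_node(node)
        parts = [c - {node} for c in communities]
        parts = [c for c in parts if c]
        if rest.number_of_edges() == 0:
            q_rest = 0.0
        else:
            q_rest = nx.community.modularity(rest, parts, weight="weight")
        g.nodes[node]["score"] = abs(q_full - q_rest)
    return _result(g, "Modularity Backbone", "score", filter_on="nodes")


# ---------------------------------------------------------------------------
# planar maximally filtered graph
# ---------------------------------------------------------------------------

def pmfg(net: nx.Graph) -> BackboneResult:
    """Greedy heaviest-edge insertion subject to planarity.

    Edges are visited by weight descending (ties lexicographic); an edge
    joins the backbone iff the backbone stays planar.  The result has at
    most 3N - 6 edges.
    """
    g = net.copy()
    planar = nx.Graph()
    planar.add_nodes_from(g.nodes)
    member: set = set()
    edges = sorted(
        g.edges(data=True), key=lambda e: (-e[2]["weight"], _edge_key(e[0], e[1]))
    )
    for u, v, d in edges:
        planar.add_edge(u, v)
        ok, _ = nx.check_planarity(planar, counterexample=False)
        if ok:
            member.add(frozenset((u, v)))
        else:
            planar.remove_edge(u, v)
    for u, v, d in g.edges(data=True):
        d["in_backbone"] = frozenset((u, v)) in member
    return _result(g, "Planar Maximally Filtered Graph", "in_backbone", boolean="in_backbone")


# ---------------------------------------------------------------------------
# similarity / centrality scores
# ---------------------------------------------------------------------------

def jaccard_sparsification(net: nx.Graph) -> BackboneResult:
    """Jaccard similarity of endpoint neighborhoods as the edge score.

    The endpoints are excluded from each other's neighbor set, so a triangle
    edge whose endpoints share their single other neighbor scores 1.
    """
    g = net.copy()
    for u, v, d in g.edges(data=True):
        nu = set(g[u]) - {v}
        nv = set(g[v]) - {u}
        union = nu | nv
        d["score"] = len(nu & nv) / len(union) if union else 0.0
    return _result(g, "Global Sparsification", "score")


def edge_betweenness(
    net: nx.Graph, distance: Callable[[float], float] = RECIPROCAL
) -> BackboneResult:
    """Weighted edge betweenness (reciprocal distances, raw pair counts)."""
    g = _with_distances(net, distance)
    betw = nx.edge_betweenness_centrality(g, weight="distance", normalized=False)
    out = net.copy()
    for (u, v), b in betw.items():
        out[u][v]["score"] = float(b)
    return _result(out, "Edge Betweenness", "score")


def node_degree(net: nx.Graph) -> BackboneResult:
    """Unweighted node degree as a node score; filtering induces subgraphs."""
    g = net.copy()
    for node, deg in g.degree():
        g.nodes[node]["score"] = float(deg)
    return _result(g, "Node Degree", "score", filter_on="nodes")
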