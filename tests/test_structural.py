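"""Structural methods against enumeration oracles and containment laws."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from netspine import (
    as_weighted_network,
    doubly_stochastic,
    edge_betweenness,
    global_threshold,
    h_backbone,
    high_salience_skeleton,
    jaccard_sparsification,
    maximum_spanning_tree,
    metric_backbone,
    modularity_vitality,
    node_degree,
    pmfg,
    primary_linkage,
    salience,
    ultrametric_backbone,
)
from netspine.datasets import random_weighted, star, triangle, two_cliques_bridge
from netspine.filters import boolean_filter, fraction_filter, threshold_filter
from netspine.structural import _hirsch


def _graph(edges):
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    return as_weighted_network(g)


def _bool_edges(result):
    return {
        frozenset((u, v))
        for u, v, d in result.graph.edges(data=True)
        if d[result.boolean_attribute]
    }


# ---------------------------------------------------------------------------
# weight-rank methods
# ---------------------------------------------------------------------------

def test_global_threshold_inclusive_counting():
    g = _graph([("a", "b", 1), ("b", "c", 2), ("c", "d", 3)])
    result = global_threshold(g)
    assert threshold_filter(result, 2).number_of_edges() == 2
    assert threshold_filter(result, 3).number_of_edges() == 1
    assert threshold_filter(result, 0.5).number_of_edges() == 3


def test_mst_triangle_by_enumeration():
    g = triangle(3, 2, 1)
    # oracle: all three spanning trees of a triangle, pick the heaviest
    edges = [(frozenset(e), g[e[0]][e[1]]["weight"]) for e in g.edges]
    best = max(itertools.combinations(edges, 2), key=lambda t: t[0][1] + t[1][1])
    assert _bool_edges(maximum_spanning_tree(g)) == {e for e, _ in best}


@pytest.mark.parametrize("seed", range(3))
def test_mst_matches_weight_of_enumerated_optimum(seed):
    g = random_weighted(6, 0.7, "uniform", seed=seed, connected=True)
    kept = _bool_edges(maximum_spanning_tree(g))
    total = sum(g[u][v]["weight"] for u, v in (tuple(e) for e in kept))
    nodes = list(g.nodes)
    best = -math.inf
    for combo in itertools.combinations(g.edges, len(nodes) - 1):
        t = nx.Graph(combo)
        if t.number_of_nodes() == len(nodes) and nx.is_tree(t):
            best = max(best, sum(g[u][v]["weight"] for u, v in combo))
    assert total == pytest.approx(best)


def test_mst_tree_input_identity():
    g = _graph([("a", "b", 1), ("b", "c", 2), ("c", "d", 3)])
    assert _bool_edges(maximum_spanning_tree(g)) == {frozenset(e) for e in g.edges}


def test_mst_forest_on_disconnected_input():
    g = _graph([("a", "b", 1), ("b", "c", 2), ("x", "y", 5)])
    assert len(_bool_edges(maximum_spanning_tree(g))) == 2 + 1


def test_primary_linkage_star_and_path():
    assert _bool_edges(primary_linkage(star(5))) == {
        frozenset(e) for e in star(5).edges
    }
    # cycle with increasing weights: only the lightest edge serves no node
    # as its per-node maximum, so exactly that edge is dropped
    g = _graph([("a", "b", 1), ("b", "c", 2), ("c", "d", 3), ("d", "a", 4)])
    assert _bool_edges(primary_linkage(g)) == {
        frozenset(("b", "c")),
        frozenset(("c", "d")),
        frozenset(("d", "a")),
    }


def test_primary_linkage_covers_all_nodes(lesmis):
    bb = boolean_filter(primary_linkage(lesmis))
    assert all(bb.degree(n) >= 1 for n in lesmis.nodes)


# ---------------------------------------------------------------------------
# doubly stochastic
# ---------------------------------------------------------------------------

def test_doubly_stochastic_row_col_sums():
    g = random_weighted(15, 0.6, "uniform", seed=8, connected=True)
    result = doubly_stochastic(g)
    nodes = list(g.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    m = np.zeros((len(nodes), len(nodes)))
    for u, v, d in result.graph.edges(data=True):
        m[idx[u], idx[v]] = m[idx[v], idx[u]] = d["score"]
    assert np.abs(m.sum(axis=0) - 1).max() < 1e-5
    assert np.abs(m.sum(axis=1) - 1).max() < 1e-5


def test_doubly_stochastic_fixed_point():
    # a cycle with equal weights scales to exactly 1/2 per edge
    g = nx.cycle_graph(6)
    nx.set_edge_attributes(g, 1.0, "weight")
    result = doubly_stochastic(as_weighted_network(g))
    assert all(
        d["score"] == pytest.approx(0.5) for _, _, d in result.graph.edges(data=True)
    )


def test_doubly_stochastic_boolean_spans_and_connects():
    g = random_weighted(12, 0.5, "uniform", seed=5, connected=True)
    bb = boolean_filter(doubly_stochastic(g))
    assert set(bb.nodes) == set(g.nodes)
    assert nx.is_connected(bb)


def test_doubly_stochastic_nonconvergence_raises(lesmis):
    # seven degree-one neighbors of one hub make the scaling infeasible
    with pytest.raises(RuntimeError, match="converge"):
        doubly_stochastic(lesmis)


# ---------------------------------------------------------------------------
# salience
# ---------------------------------------------------------------------------

def test_salience_tree_input_all_one():
    g = _graph([("a", "b", 1), ("b", "c", 2), ("b", "d", 5)])
    assert set(salience(g).values()) == {1.0}


def test_salience_equal_triangle_two_thirds():
    sal = salience(triangle(1, 1, 1))
    assert all(v == pytest.approx(2 / 3) for v in sal.values())


@pytest.mark.parametrize("seed", range(3))
def test_salience_matches_tree_enumeration(seed):
    """Oracle: explicitly build each root's union-of-shortest-paths tree by
    enumerating all simple paths (weights distinct, so trees are unique)."""
    g = random_weighted(8, 0.5, "uniform", seed=seed, distinct=True, connected=True)
    for u, v, d in g.edges(data=True):
        d["dist"] = 1 / d["weight"]
    n = g.number_of_nodes()
    count = {frozenset(e): 0 for e in g.edges}
    for root in g.nodes:
        tree = set()
        for target in g.nodes:
            if target == root:
                continue
            best = min(
                nx.all_simple_paths(g, root, target),
                key=lambda p: sum(g[a][b]["dist"] for a, b in zip(p, p[1:])),
            )
            tree.update(frozenset(e) for e in zip(best, best[1:]))
        for e in tree:
            count[e] += 1
    expected = {e: c / n for e, c in count.items()}
    got = {frozenset(e): v for e, v in salience(g).items()}
    assert got == pytest.approx(expected)


def test_salience_values_are_multiples_of_one_over_n(lesmis):
    n = lesmis.number_of_nodes()
    for v in salience(lesmis).values():
        assert (v * n) == pytest.approx(round(v * n))
        assert 0 <= v <= 1


def test_hss_boolean_rule(lesmis):
    result = high_salience_skeleton(lesmis)
    kept = _bool_edges(result)
    assert kept == {
        frozenset((u, v))
        for u, v, d in result.graph.edges(data=True)
        if d["score"] > 0.8
    }


# ---------------------------------------------------------------------------
# h-backbone
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "values,expected",
    [([5, 4, 3, 2, 1], 3), ([0.5, 0.4], 0), ([10, 10], 2), ([1], 1), ([], 0)],
)
def test_hirsch_rule(values, expected):
    assert _hirsch(values) == expected


def test_h_backbone_contains_h_strength():
    g = _graph(
        [("a", "b", 5), ("b", "c", 4), ("c", "d", 3), ("d", "e", 2), ("e", "a", 1)]
    )
    kept = _bool_edges(h_backbone(g))
    h_strength = {frozenset(e) for e in g.edges if g[e[0]][e[1]]["weight"] >= 3}
    assert h_strength <= kept


def test_h_backbone_all_small_weights_strength_empty():
    g = _graph([("a", "b", 0.5), ("b", "c", 0.4), ("c", "a", 0.3)])
    result = h_backbone(g)
    # h-strength empty; any kept edge must come from the bridge rule
    for u, v, d in result.graph.edges(data=True):
        if d["in_backbone"]:
            assert d["bridge"] >= 1


# ---------------------------------------------------------------------------
# metric / ultrametric backbones
# ---------------------------------------------------------------------------

def test_distance_backbones_on_uneven_triangle():
    # distances (1, 1, 1.5): the long edge is metric (1.5 < 2) but not
    # ultrametric (1.5 > max(1, 1))
    g = triangle(1, 1, 2 / 3)
    metric = _bool_edges(metric_backbone(g))
    ultra = _bool_edges(ultrametric_backbone(g))
    assert metric == {frozenset(e) for e in g.edges}
    assert ultra == {frozenset(("a", "b")), frozenset(("b", "c"))}


def test_tree_input_kept_by_both():
    g = _graph([("a", "b", 1), ("b", "c", 5), ("b", "d", 2)])
    assert _bool_edges(metric_backbone(g)) == {frozenset(e) for e in g.edges}
    assert _bool_edges(ultrametric_backbone(g)) == {frozenset(e) for e in g.edges}


@pytest.mark.parametrize("seed", range(3))
def test_distance_backbones_match_path_enumeration(seed):
    g = random_weighted(7, 0.5, "uniform", seed=seed, distinct=True, connected=True)
    for u, v, d in g.edges(data=True):
        d["dist"] = 1 / d["weight"]
    metric_expected, ultra_expected = set(), set()
    for u, v in g.edges:
        direct = g[u][v]["dist"]
        indirect = [
            p
            for p in nx.all_simple_paths(g, u, v)
            if len(p) > 2
        ]
        sums = [sum(g[a][b]["dist"] for a, b in zip(p, p[1:])) for p in indirect]
        maxs = [max(g[a][b]["dist"] for a, b in zip(p, p[1:])) for p in indirect]
        if not sums or direct <= min(sums):
            metric_expected.add(frozenset((u, v)))
        if not maxs or direct <= min(maxs):
            ultra_expected.add(frozenset((u, v)))
    assert _bool_edges(metric_backbone(g)) == metric_expected
    assert _bool_edges(ultrametric_backbone(g)) == ultra_expected


@pytest.mark.parametrize("seed", range(4))
def test_containment_chain_distinct_weights(seed):
    g = random_weighted(12, 0.4, "uniform", seed=seed, distinct=True, connected=True)
    mst = _bool_edges(maximum_spanning_tree(g))
    ultra = _bool_edges(ultrametric_backbone(g))
    metric = _bool_edges(metric_backbone(g))
    alle = {frozenset(e) for e in g.edges}
    assert mst <= ultra <= metric <= alle


def test_ultrametric_invariant_to_distance_map(distinct_weight_graph):
    g = distinct_weight_graph
    a = _bool_edges(ultrametric_backbone(g, distance=lambda w: 1 / w))
    b = _bool_edges(ultrametric_backbone(g, distance=lambda w: 1 / (w * w)))
    c = _bool_edges(ultrametric_backbone(g, distance=lambda w: math.exp(-w)))
    assert a == b == c


# ---------------------------------------------------------------------------
# modularity vitality
# ---------------------------------------------------------------------------

def test_modularity_vitality_symmetry():
    g = two_cliques_bridge(4)
    result = modularity_vitality(g)
    scores = result.property_values()
    # nodes a2..a4 are interchangeable, as are b2..b4
    assert scores["a2"] == pytest.approx(scores["a3"]) == pytest.approx(scores["a4"])
    assert scores["b2"] == pytest.approx(scores["b3"]) == pytest.approx(scores["b4"])
    assert scores["a1"] == pytest.approx(scores["b1"])


def test_modularity_vitality_matches_direct_q_formula():
    """Oracle: recompute Q = Σ_c (in_c/m - (tot_c/2m)²) by hand per removal."""
    g = random_weighted(12, 0.4, "uniform", seed=13, connected=True)
    communities = nx.community.louvain_communities(g, weight="weight", seed=42)

    def q_of(graph, parts):
        m = graph.size(weight="weight")
        total = 0.0
        for part in parts:
            inside = sum(
                d["weight"]
                for u, v, d in graph.edges(data=True)
                if u in part and v in part
            )
            tot = sum(graph.degree(n, weight="weight") for n in part)
            total += inside / m - (tot / (2 * m)) ** 2
        return total

    q_full = q_of(g, communities)
    result = modularity_vitality(g)
    for node, score in result.property_values().items():
        rest = g.copy()
        rest.remove_node(node)
        parts = [c - {node} for c in communities if c - {node}]
        assert score == pytest.approx(abs(q_full - q_of(rest, parts)), abs=1e-12)


def test_modularity_fraction_keeps_top_nodes():
    g = two_cliques_bridge(5)
    result = modularity_vitality(g)
    bb = fraction_filter(result, 0.5)
    assert bb.number_of_nodes() == math.floor(0.5 * g.number_of_nodes())
    kept = set(bb.nodes)
    scores = result.property_values()
    assert min(scores[n] for n in kept) >= max(
        scores[n] for n in set(g.nodes) - kept
    ) - 1e-12


# ---------------------------------------------------------------------------
# PMFG
# ---------------------------------------------------------------------------

def test_pmfg_k4_all_kept():
    k4 = nx.complete_graph(4)
    for i, (u, v) in enumerate(k4.edges()):
        k4[u][v]["weight"] = float(i + 1)
    assert len(_bool_edges(pmfg(as_weighted_network(k4)))) == 6


def test_pmfg_k5_drops_lightest_edge():
    k5 = nx.complete_graph(5)
    for i, (u, v) in enumerate(k5.edges()):
        k5[u][v]["weight"] = float(i + 1)
    g = as_weighted_network(k5)
    kept = _bool_edges(pmfg(g))
    assert len(kept) == 9
    lightest = min(g.edges, key=lambda e: g[e[0]][e[1]]["weight"])
    assert frozenset(lightest) not in kept


@pytest.mark.parametrize("seed", range(3))
def test_pmfg_output_planar_and_bounded(seed):
    g = random_weighted(12, 0.6, "uniform", seed=seed)
    bb = boolean_filter(pmfg(g), drop_isolates=True)
    ok, _ = nx.check_planarity(bb)
    assert ok
    assert bb.number_of_edges() <= 3 * g.number_of_nodes() - 6


# ---------------------------------------------------------------------------
# jaccard, betweenness, degree
# ---------------------------------------------------------------------------

def test_jaccard_triangle_and_disjoint():
    g = _graph([("a", "b", 1), ("b", "c", 1), ("a", "c", 1), ("c", "d", 1)])
    scores = jaccard_sparsification(g).property_values()
    assert scores[("a", "b")] == 1.0  # both see exactly {c}
    assert scores[("c", "d")] == 0.0  # d has no other neighbors


def test_jaccard_complete_graph_symmetric():
    g = nx.complete_graph(5)
    nx.set_edge_attributes(g, 2.0, "weight")
    assert len(set(jaccard_sparsification(as_weighted_network(g)).property_values().values())) == 1


def _betweenness_brute(g):
    """Oracle: all-pairs enumeration of shortest paths over 1/w distances."""
    for u, v, d in g.edges(data=True):
        d["dist"] = 1 / d["weight"]
    nodes = list(g.nodes)
    out = {frozenset(e): 0.0 for e in g.edges}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            paths = list(nx.all_simple_paths(g, s, t))
            lengths = [
                sum(g[a][b]["dist"] for a, b in zip(p, p[1:])) for p in paths
            ]
            lo = min(lengths)
            shortest = [
                p for p, L in zip(paths, lengths) if L < lo * (1 + 1e-12)
            ]
            for p in shortest:
                for e in zip(p, p[1:]):
                    out[frozenset(e)] += 1.0 / len(shortest)
    return out


@pytest.mark.parametrize("seed", range(2))
def test_edge_betweenness_matches_enumeration(seed):
    g = random_weighted(7, 0.5, "uniform", seed=seed, distinct=True, connected=True)
    expected = _betweenness_brute(g.copy())
    got = {frozenset(e): v for e, v in edge_betweenness(g).property_values().items()}
    assert got == pytest.approx(expected)


def test_bridge_edge_has_maximal_betweenness():
    g = two_cliques_bridge(4)
    scores = edge_betweenness(g).property_values()
    bridge = scores[("a1", "b1")] if ("a1", "b1") in scores else scores[("b1", "a1")]
    assert bridge == max(scores.values())


def test_node_degree_star_center():
    g = star(6)
    scores = node_degree(g).property_values()
    assert scores["c"] == 6.0
    assert all(scores[f"v{i}"] == 1.0 for i in range(1, 7))


# ---------------------------------------------------------------------------
# generic containment
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "method",
    [maximum_spanning_tree, primary_linkage, pmfg, metric_backbone,
     ultrametric_backbone, h_backbone],
)
def test_boolean_outputs_are_subgraphs(method, distinct_weight_graph):
    g = distinct_weight_graph
    bb = boolean_filter(method(g))
    assert set(bb.nodes) <= set(g.nodes)
    for u, v, d in bb.edges(data=True):
        assert g.has_edge(u, v)
        assert d["weight"] == g[u][v]["weight"]
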