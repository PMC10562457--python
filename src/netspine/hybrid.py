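"""Hybrid backbone extraction: path involvement meets a statistical null.

The globally and locally adaptive backbone (GLAB) scores each edge, from the
viewpoint of each endpoint, by its *involvement*: the fraction of all
shortest paths from that node to the rest of the network that traverse the
edge.  A null distribution on involvements then converts the observation
into a p-value, with the node's degree (raised to the power ``c``) acting as
the effective sample size.
"""

from __future__ import annotations

from typing import Callable

import networkx as nx
import numpy as np
from scipy import stats

from .backbone import FILTER_COMPATIBILITY, BackboneResult
from .structural import RECIPROCAL, _edge_key, _with_distances

__all__ = ["involvement", "glab"]


def involvement(
    net: nx.Graph, distance: Callable[[float], float] = RECIPROCAL
) -> dict:
    """Per (root, incident edge) involvement fractions.

    Returns a dict mapping each node v to a dict over its incident edges
    (keyed by the neighbor u) with the fraction of shortest paths from v to
    all other nodes whose first hop is the edge (v, u).  All shortest paths
    are counted with multiplicity.
    """
    g = _with_distances(net, distance)
    out: dict = {}
    for root in g.nodes:
        pred, dist = nx.dijkstra_predecessor_and_distance(g, root, weight="distance")
        order = sorted(dist, key=dist.get)  # ascending distance = topological
        # sigma[t]: number of shortest root->t paths
        sigma = {root: 1.0}
        for t in order[1:]:
            sigma[t] = sum(sigma[p] for p in pred[t])
        total = sum(sigma[t] for t in order[1:])
        inv: dict = {}
        for first_hop in g[root]:
            if root not in pred.get(first_hop, []):
                inv[first_hop] = 0.0
                continue
            # nu[t]: number of shortest root->t paths starting with (root, first_hop)
            nu = {root: 0.0}
            for t in order[1:]:
                nu[t] = sum(nu[p] for p in pred[t])
                if t == first_hop:
                    nu[t] += 1.0
            through = sum(nu[t] for t in order[1:])
            inv[first_hop] = through / total if total else 0.0
        out[root] = inv
    return out


def _uniform_tail(x: float, k_eff: float) -> float:
    if k_eff <= 1.0:
        return 1.0
    return float(np.clip((1.0 - x) ** (k_eff - 1.0), 0.0, 1.0))


def _gaussian_tail(x: float, sample: np.ndarray) -> float:
    mu, sd = float(sample.mean()), float(sample.std(ddof=0))
    if sd == 0.0:
        return 1.0 if x <= mu else 0.0
    return float(stats.norm.sf(x, loc=mu, scale=sd))


def _powerlaw_tail(x: float, sample: np.ndarray) -> float:
    pos = sample[sample > 0]
    if len(pos) < 2:
        return 1.0
    xmin = float(pos.min())
    if x <= xmin:
        return 1.0
    # continuous Pareto MLE for the exponent
    alpha = 1.0 + len(pos) / float(np.sum(np.log(pos / xmin)))
    return float(np.clip((x / xmin) ** (1.0 - alpha), 0.0, 1.0))


def glab(
    net: nx.Graph,
    c: float = 1.0,
    null: str = "uniform",
    distance: Callable[[float], float] = RECIPROCAL,
) -> BackboneResult:
    """Globally and locally adaptive backbone (p-values on edges).

    Parameters
    ----------
    net
        Weighted network (distances are reciprocal weights by default).
    c
        Degree-influence exponent: node v's null uses an effective sample
        size k_v**c, so hubs judge the same involvement more harshly when
        c > 0.
    null
        Null family for the involvement: ``"uniform"`` (closed-form tail
        (1 - x)^(k_v^c - 1)), ``"gaussian"`` or ``"powerlaw"`` (both
        moment/MLE-fitted to the node's own involvement sample).

    The edge p-value is the minimum of its two endpoint p-values.
    """
    if c < 0:
        raise ValueError("c must be nonnegative")
    if null not in ("uniform", "gaussian", "powerlaw"):
        raise ValueError(f"unknown null family {null!r}")
    if net.number_of_edges() == 0:
        raise ValueError("graph has no edges")
    inv = involvement(net, distance)
    g = net.copy()
    endpoint_p: dict = {}
    for root, edges in inv.items():
        k_eff = float(nx.degree(g, root)) ** c
        sample = np.array(list(edges.values()))
        for nbr, x in edges.items():
            if null == "uniform":
                p = _uniform_tail(x, k_eff)
            elif null == "gaussian":
                p = _gaussian_tail(x, sample)
            else:
                p = _powerlaw_tail(x, sample)
            endpoint_p[(root, nbr)] = p
    for u, v, d in g.edges(data=True):
        pu, pv = endpoint_p[(u, v)], endpoint_p[(v, u)]
        d["involvement"] = (
            (inv[u][v], inv[v][u]) if u <= v else (inv[v][u], inv[u][v])
        )
        d["p_value"] = float(min(pu, pv))
    return BackboneResult(
        graph=g,
        method_name="Globally and Locally Adaptive Backbone",
        property_name="p_value",
        is_pvalue=True,
        compatible_filters=FILTER_COMPATIBILITY["Globally and Locally Adaptive Backbone"],
    )
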