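"""Evaluation measures for (original, backbone) pairs and single graphs.

Fractions compare a backbone with the network it came from; density, average
degree and reachability describe one graph; the two-sample
Kolmogorov–Smirnov statistic compares property distributions (edge weights,
node degrees) between graphs.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
from scipy import stats

__all__ = [
    "node_fraction",
    "edge_fraction",
    "weight_fraction",
    "density",
    "average_degree",
    "reachability",
    "ks_statistic",
    "edge_weights",
    "node_degrees",
    "BUILTIN_MEASURES",
]


def _non_isolated(net: nx.Graph) -> int:
    return sum(1 for _, d in net.degree() if d > 0)


def node_fraction(original: nx.Graph, backbone: nx.Graph) -> float:
    """Fraction of the original's nodes that keep at least one edge.

    Counting non-isolated nodes makes edge-targeted filters (which carry all
    original nodes along) report honestly which nodes the backbone still
    serves.
    """
    if original.number_of_nodes() == 0:
        raise ValueError("original network is empty")
    return _non_isolated(backbone) / original.number_of_nodes()


def edge_fraction(original: nx.Graph, backbone: nx.Graph) -> float:
    if original.number_of_edges() == 0:
        raise ValueError("original network has no edges")
    return backbone.number_of_edges() / original.number_of_edges()


def weight_fraction(original: nx.Graph, backbone: nx.Graph) -> float:
    total = original.size(weight="weight")
    if total == 0:
        raise ValueError("original network has no weight")
    return backbone.size(weight="weight") / total


def density(net: nx.Graph) -> float:
    """ρ = 2E / N(N-1)."""
    return nx.density(net)


def average_degree(net: nx.Graph) -> float:
    """⟨k⟩ = 2E / N."""
    n = net.number_of_nodes()
    return 2.0 * net.number_of_edges() / n if n else 0.0


def reachability(net: nx.Graph) -> float:
    """Fraction of ordered node pairs joined by a path (1 when connected,
    0 when every node is isolated)."""
    n = net.number_of_nodes()
    if n < 2:
        return 1.0 if n == 1 else 0.0
    pairs = sum(
        len(c) * (len(c) - 1) for c in nx.connected_components(net)
    )
    return pairs / (n * (n - 1))


def ks_statistic(sample_a, sample_b) -> float:
    """Two-sample Kolmogorov–Smirnov statistic D = max_x |F(x) - G(x)|."""
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS statistic needs nonempty samples")
    with warnings.catch_warnings():
        # only the statistic is used; scipy may warn while computing the
        # p-value on heavily tied samples
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(stats.ks_2samp(a, b).statistic)


# -- distribution extractors -------------------------------------------------

def edge_weights(net: nx.Graph) -> list[float]:
    return [d["weight"] for _, _, d in net.edges(data=True)]


def node_degrees(net: nx.Graph) -> list[float]:
    """Degrees of non-isolated nodes (isolates are bookkeeping artifacts of
    edge-targeted filters, not part of the degree distribution)."""
    return [float(d) for _, d in net.degree() if d > 0]


#: (original, backbone) -> scalar versions of the built-in measures, in the
#: order comparison tables print them.
BUILTIN_MEASURES = {
    "Reachability": lambda o, b: reachability(b),
    "Node Fraction": node_fraction,
    "Edge Fraction": edge_fraction,
    "Weight Fraction": weight_fraction,
    "Density": lambda o, b: density(b),
    "Average Degree": lambda o, b: average_degree(b),
}
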