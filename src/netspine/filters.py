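"""Turn a scored :class:`BackboneResult` into an extracted backbone graph.

Three rules: the method's native boolean rule, a threshold on the score or
p-value, and a top-fraction cut.  Each method admits only some of them (see
:data:`netspine.backbone.FILTER_COMPATIBILITY`); incompatible calls raise.

Conventions, applied uniformly: p-value thresholds are strict (< α, the
significance level excludes p = α); score thresholds are inclusive (≥ β);
fraction cuts keep ⌊f·M⌋ elements with ties at the cut resolved stably in
the order elements appear in the graph.  Edge-targeted
filters keep every original node by default so that node counts report
isolation honestly; pass ``drop_isolates=True`` to prune isolated nodes.
"""

from __future__ import annotations

import math

import networkx as nx

from .backbone import BOOLEAN, FRACTION, THRESHOLD, BackboneResult

__all__ = ["boolean_filter", "threshold_filter", "fraction_filter", "apply_filter"]


def _check_compatible(result: BackboneResult, kind: str) -> None:
    if kind not in result.compatible_filters:
        raise ValueError(
            f"{result.method_name} does not admit the {kind} filter; "
            f"compatible: {sorted(result.compatible_filters)}"
        )


def _extract_edges(result: BackboneResult, kept_edges, drop_isolates: bool) -> nx.Graph:
    bb = nx.Graph()
    if not drop_isolates:
        bb.add_nodes_from(result.graph.nodes)
    for u, v in kept_edges:
        bb.add_edge(u, v, weight=result.graph[u][v]["weight"])
    bb.graph["method"] = result.method_name
    return bb


def _extract_nodes(result: BackboneResult, kept_nodes) -> nx.Graph:
    bb = result.graph.subgraph(kept_nodes).copy()
    out = nx.Graph()
    out.add_nodes_from(bb.nodes)
    for u, v, d in bb.edges(data=True):
        out.add_edge(u, v, weight=d["weight"])
    out.graph["method"] = result.method_name
    return out


def boolean_filter(result: BackboneResult, *, drop_isolates: bool = False) -> nx.Graph:
    """Extract the method's native single substructure."""
    _check_compatible(result, BOOLEAN)
    attr = result.boolean_attribute
    if result.filter_on == "nodes":
        kept = [n for n, d in result.graph.nodes(data=True) if d[attr]]
        return _extract_nodes(result, kept)
    kept = [(u, v) for u, v, d in result.graph.edges(data=True) if d[attr]]
    return _extract_edges(result, kept, drop_isolates)


def threshold_filter(
    result: BackboneResult, threshold: float, *, drop_isolates: bool = False
) -> nx.Graph:
    """Keep p-values strictly below, or scores at or above, the threshold."""
    _check_compatible(result, THRESHOLD)
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")

    if result.is_pvalue:
        keep = lambda v: v < threshold  # noqa: E731
    else:
        keep = lambda v: v >= threshold  # noqa: E731
    values = result.property_values()
    if result.filter_on == "nodes":
        return _extract_nodes(result, [n for n, v in values.items() if keep(v)])
    return _extract_edges(
        result, [e for e, v in values.items() if keep(v)], drop_isolates
    )


def fraction_filter(
    result: BackboneResult, fraction: float, *, drop_isolates: bool = False
) -> nx.Graph:
    """Keep the best ⌊fraction·M⌋ elements (lowest p-values / highest scores)."""
    _check_compatible(result, FRACTION)
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    values = result.property_values()
    count = math.floor(fraction * len(values))
    sign = 1.0 if result.is_pvalue else -1.0
    # stable sort: ties resolved by element discovery order in the graph,
    # so runs on the same input are reproducible
    ranked = sorted(values, key=lambda e: sign * values[e])
    if result.filter_on == "nodes":
        return _extract_nodes(result, ranked[:count])
    return _extract_edges(result, ranked[:count], drop_isolates)


def apply_filter(result: BackboneResult, kind: str, parameter: float | None = None, **kw) -> nx.Graph:
    """Dispatch on a filter kind name (used by the CLI and Compare)."""
    if kind == BOOLEAN:
        return boolean_filter(result, **kw)
    if kind == THRESHOLD:
        return threshold_filter(result, parameter, **kw)
    if kind == FRACTION:
        return fraction_filter(result, parameter, **kw)
    raise ValueError(f"unknown filter kind {kind!r}")
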