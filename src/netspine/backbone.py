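"""Core result container handed from extraction methods to filters.

Every backbone extraction method returns a :class:`BackboneResult`: the input
graph annotated with a per-edge (or per-node) property — a p-value for
statistical methods, a score for structural ones, or a boolean membership flag
for methods that define a single substructure.  Filtering is deliberately
separated from scoring: the same result can be thresholded, cut to a fraction,
or reduced to its method's native boolean rule, as far as the method's
compatibility allows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

#: The three filter kinds.
BOOLEAN = "boolean"
THRESHOLD = "threshold"
FRACTION = "fraction"

FILTER_KINDS = frozenset({BOOLEAN, THRESHOLD, FRACTION})

#: Which filters each built-in method admits.  Methods that define a single
#: substructure are boolean-only; score/p-value methods admit threshold and
#: fraction cuts; the doubly stochastic and high salience skeleton methods
#: carry both a score and a native boolean rule.
FILTER_COMPATIBILITY: dict[str, frozenset[str]] = {
    "Disparity Filter": frozenset({FRACTION, THRESHOLD}),
    "Noise Corrected Filter": frozenset({FRACTION, THRESHOLD}),
    "Marginal Likelihood Filter": frozenset({FRACTION, THRESHOLD}),
    "Enhanced Configuration Model Filter": frozenset({FRACTION, THRESHOLD}),
    "Locally Adaptive Network Sparsification Filter": frozenset({FRACTION, THRESHOLD}),
    "Multiple Linkage Analysis": frozenset({BOOLEAN}),
    "Global Threshold Filter": frozenset({FRACTION, THRESHOLD}),
    "Maximum Spanning Tree": frozenset({BOOLEAN}),
    "Doubly Stochastic Filter": frozenset({BOOLEAN, FRACTION, THRESHOLD}),
    "High Salience Skeleton": frozenset({BOOLEAN, FRACTION, THRESHOLD}),
    "h-Backbone": frozenset({BOOLEAN}),
    "Metric Backbone": frozenset({BOOLEAN}),
    "Ultrametric Backbone": frozenset({BOOLEAN}),
    "Modularity Backbone": frozenset({FRACTION, THRESHOLD}),
    "Planar Maximally Filtered Graph": frozenset({BOOLEAN}),
    "Primary Linkage Analysis": frozenset({BOOLEAN}),
    "Global Sparsification": frozenset({FRACTION, THRESHOLD}),
    "Edge Betweenness": frozenset({FRACTION, THRESHOLD}),
    "Node Degree": frozenset({FRACTION, THRESHOLD}),
    "Globally and Locally Adaptive Backbone": frozenset({FRACTION, THRESHOLD}),
}


@dataclass(frozen=True)
class FilterSpec:
    """A filter kind plus its parameter.

    ``parameter`` is the score/p-value threshold for ``threshold`` filters,
    the retained fraction f in (0, 1] for ``fraction`` filters, and unused
    for ``boolean`` filters.
    """

    kind: str
    parameter: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in FILTER_KINDS:
            raise ValueError(
                f"unknown filter kind {self.kind!r}; expected one of {sorted(FILTER_KINDS)}"
            )
        if self.kind == FRACTION:
            if self.parameter is None or not 0 < self.parameter <= 1:
                raise ValueError("fraction filter requires a parameter in (0, 1]")
        if self.kind == THRESHOLD:
            if self.parameter is None or not pd.notna(self.parameter):
                raise ValueError("threshold filter requires a finite parameter")


@dataclass
class BackboneResult:
    """Annotated graph returned by every extraction method.

    Parameters
    ----------
    graph
        The original graph with the method's property attached to its edges
        (``filter_on == "edges"``) or nodes (``filter_on == "nodes"``).
    method_name
        Human-readable method name; also keys the compatibility table.
    property_name
        Name of the edge/node attribute holding the p-value, score, or flag.
    is_pvalue
        True when the property is a p-value (filtered as "keep smaller").
    compatible_filters
        Subset of ``{"boolean", "threshold", "fraction"}``.
    filter_on
        ``"edges"`` or ``"nodes"``.
    boolean_attribute
        Name of the boolean edge/node attribute implementing the method's
        native rule (for boolean-capable methods).  Defaults to
        ``property_name`` when the property itself is boolean.
    """

    graph: nx.Graph
    method_name: str
    property_name: str
    is_pvalue: bool
    compatible_filters: frozenset[str]
    filter_on: str = "edges"
    boolean_attribute: str | None = field(default=None)

    def __post_init__(self) -> None:
        self.compatible_filters = frozenset(self.compatible_filters)
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.filter_on not in ("edges", "nodes"):
            raise ValueError("filter_on must be 'edges' or 'nodes'")
        if not self.compatible_filters:
            raise ValueError("compatible_filters must be nonempty")
        unknown = self.compatible_filters - FILTER_KINDS
        if unknown:
            raise ValueError(f"unknown filter kinds: {sorted(unknown)}")
        values = list(self.property_values().values())
        if not values and self.graph.number_of_nodes():
            raise ValueError(
                f"property {self.property_name!r} missing from {self.filter_on}"
            )
        if self.is_pvalue:
            bad = [v for v in values if not 0.0 <= float(v) <= 1.0]
            if bad:
                raise ValueError(
                    f"{self.method_name}: p-values must lie in [0, 1]; got {bad[:3]}"
                )
        if self.boolean_attribute is None and values and all(
            isinstance(v, (bool,)) for v in values
        ):
            self.boolean_attribute = self.property_name
        if BOOLEAN in self.compatible_filters and self.boolean_attribute is None:
            raise ValueError(
                f"{self.method_name}: boolean-capable result needs a boolean attribute"
            )

    # -- views -----------------------------------------------------------
    def property_values(self, name: str | None = None) -> dict:
        """Property value keyed by edge tuple or node id."""
        name = name or self.property_name
        if self.filter_on == "nodes":
            return {n: d[name] for n, d in self.graph.nodes(data=True) if name in d}
        return {
            (u, v): d[name] for u, v, d in self.graph.edges(data=True) if name in d
        }

    def to_dataframe(self) -> pd.DataFrame:
        """One row per edge (or node): identifiers, weight, the in-backbone
        flag under the method's default rule, and the property value."""
        value_col = "P-value" if self.is_pvalue else "Score"
        rows = []
        if self.filter_on == "nodes":
            for n, d in self.graph.nodes(data=True):
                rows.append(
                    {
                        "Node": n,
                        self.method_name: self._default_flag(d),
                        value_col: d[self.property_name],
                    }
                )
            return pd.DataFrame(rows, columns=["Node", self.method_name, value_col])
        for u, v, d in self.graph.edges(data=True):
            rows.append(
                {
                    "Source": u,
                    "Target": v,
                    "Weight": d.get("weight"),
                    self.method_name: self._default_flag(d),
                    value_col: d[self.property_name],
                }
            )
        return pd.DataFrame(
            rows, columns=["Source", "Target", "Weight", self.method_name, value_col]
        )

    def _default_flag(self, data: dict) -> bool:
        if self.boolean_attribute is not None:
            return bool(data[self.boolean_attribute])
        if self.is_pvalue:
            return bool(data[self.property_name] < 0.05)
        return True


def result_to_table(result: BackboneResult) -> pd.DataFrame:
    """Module-level alias for :meth:`BackboneResult.to_dataframe`."""
    return result.to_dataframe()
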