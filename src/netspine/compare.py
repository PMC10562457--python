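"""Comparison framework: property tables, progressions, distribution
distances, consensual backbones, and user plug-ins.

A :class:`Compare` session holds one original network, an ordered set of
:class:`~netspine.backbone.BackboneResult` objects (built-in or user
supplied) and an ordered set of evaluation measures.  Methods incompatible
with a requested filter are skipped with a warning rather than aborting the
whole table.
"""

from __future__ import annotations

import logging
from typing import Callable

import networkx as nx
import pandas as pd

from .backbone import BackboneResult, FilterSpec
from .filters import apply_filter
from .measures import BUILTIN_MEASURES, ks_statistic

__all__ = ["Compare", "consensus"]

log = logging.getLogger(__name__)


def consensus(
    backbones: list[nx.Graph],
    original: nx.Graph | None = None,
    *,
    drop_isolates: bool = False,
) -> nx.Graph:
    """Consensual backbone: intersection of node sets and edge sets.

    Weights are taken from ``original`` when given, else from the first
    backbone.  With ``drop_isolates`` nodes isolated in the intersection are
    removed.
    """
    if not backbones:
        raise ValueError("consensus needs at least one backbone")
    nodes = set(backbones[0].nodes)
    edges = {frozenset(e) for e in backbones[0].edges}
    for bb in backbones[1:]:
        nodes &= set(bb.nodes)
        edges &= {frozenset(e) for e in bb.edges}
    source = original if original is not None else backbones[0]
    out = nx.Graph()
    out.add_nodes_from(nodes)
    for e in edges:
        u, v = tuple(e)
        if u in nodes and v in nodes:
            out.add_edge(u, v, weight=source[u][v]["weight"])
    if drop_isolates:
        out.remove_nodes_from([n for n in out.nodes if out.degree(n) == 0])
    return out


class Compare:
    """Comparison session over one original network.

    Parameters
    ----------
    original
        The weighted network every backbone was extracted from.
    measures
        Optional mapping name -> callable ``(original, backbone) -> scalar``;
        defaults to the built-in evaluation measures.
    """

    def __init__(self, original: nx.Graph, measures: dict | None = None):
        if original.number_of_nodes() == 0:
            raise ValueError("original network is empty")
        self.original = original
        self.results: dict[str, BackboneResult] = {}
        self.measures: dict[str, Callable] = dict(
            measures if measures is not None else BUILTIN_MEASURES
        )

    # -- registration ----------------------------------------------------
    def add_backbone(self, result: BackboneResult, name: str | None = None) -> "Compare":
        """Register a method result (user plug-ins welcome; validated)."""
        if not isinstance(result, BackboneResult):
            raise TypeError(
                "add_backbone expects a BackboneResult; user methods must wrap "
                "their annotated graph in one"
            )
        result.validate()
        self.results[name or result.method_name] = result
        return self

    def add_measure(self, name: str, fn: Callable) -> "Compare":
        """Register an evaluation measure ``(original, backbone) -> scalar``."""
        if not callable(fn):
            raise TypeError("measure must be callable")
        self.measures[name] = fn
        return self

    # -- tables ----------------------------------------------------------
    def _filtered(self, spec: FilterSpec):
        for name, result in self.results.items():
            if spec.kind not in result.compatible_filters:
                log.warning(
                    "skipping %s: %s filter not applicable", name, spec.kind
                )
                continue
            yield name, apply_filter(result, spec.kind, spec.parameter)

    def properties(self, spec: FilterSpec) -> pd.DataFrame:
        """Measure table: first row the original network, one row per
        compatible backbone."""
        if not self.results:
            raise ValueError("no backbones in the session")
        rows = {
            "Original Network": {
                m: fn(self.original, self.original) for m, fn in self.measures.items()
            }
        }
        for name, bb in self._filtered(spec):
            rows[name] = {m: fn(self.original, bb) for m, fn in self.measures.items()}
        return pd.DataFrame.from_dict(rows, orient="index")[list(self.measures)]

    def properties_progression(
        self, filter_kind: str, values: list[float]
    ) -> dict[str, pd.DataFrame]:
        """Evolution of each measure as the filter parameter sweeps ``values``.

        Returns one DataFrame per measure: rows are parameter values,
        columns are methods.
        """
        if not values:
            raise ValueError("values must be nonempty")
        tables = {m: {} for m in self.measures}
        for value in values:
            spec = FilterSpec(filter_kind, value)
            for name, bb in self._filtered(spec):
                for m, fn in self.measures.items():
                    tables[m].setdefault(name, {})[value] = fn(self.original, bb)
        return {
            m: pd.DataFrame(cols).reindex(values)
            for m, cols in tables.items()
        }

    def distribution_ks_statistic(
        self, extractor: Callable[[nx.Graph], list], spec: FilterSpec
    ) -> pd.DataFrame:
        """KS statistic between the original's and each backbone's
        distribution of ``extractor`` values (e.g. edge weights, degrees)."""
        base = list(extractor(self.original))
        if not base:
            raise ValueError("extractor returned an empty sample for the original")
        rows = {}
        for name, bb in self._filtered(spec):
            sample = list(extractor(bb))
            if not sample:
                raise ValueError(f"extractor returned an empty sample for {name}")
            rows[name] = ks_statistic(base, sample)
        return pd.DataFrame.from_dict(rows, orient="index", columns=["KS statistic"])

    def consensus(self, spec: FilterSpec, *, drop_isolates: bool = False) -> nx.Graph:
        """Consensual backbone of every compatible method under ``spec``."""
        backbones = [bb for _, bb in self._filtered(spec)]
        if not backbones:
            raise ValueError("no compatible backbones for this filter")
        return consensus(backbones, self.original, drop_isolates=drop_isolates)
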