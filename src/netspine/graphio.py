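"""Readers, writers and validation for simple undirected weighted networks.

The in-memory container is a plain :class:`networkx.Graph` whose edges carry a
strictly positive, finite ``weight`` attribute.  Node identifiers are opaque
strings; numeric labels in input files are normalized to strings so that
``1`` and ``"1"`` never denote different nodes.
"""

from __future__ import annotations

import math
from os import PathLike

import networkx as nx
import pandas as pd

__all__ = [
    "as_weighted_network",
    "read_edgelist",
    "write_edgelist",
    "read_graphml",
    "write_graphml",
    "require_integer_weights",
]


def _check_weight(u, v, w) -> float:
    try:
        w = float(w)
    except (TypeError, ValueError):
        raise ValueError(f"edge ({u!r}, {v!r}): non-numeric weight {w!r}") from None
    if math.isnan(w) or math.isinf(w):
        raise ValueError(f"edge ({u!r}, {v!r}): weight must be finite, got {w}")
    if w <= 0:
        raise ValueError(f"edge ({u!r}, {v!r}): weight must be positive, got {w}")
    return w


def as_weighted_network(
    data,
    *,
    duplicates: str = "error",
    drop_self_loops: bool = False,
) -> nx.Graph:
    """Build a validated weighted network from a graph or an edge table.

    Parameters
    ----------
    data
        A :class:`networkx.Graph` with ``weight`` edge attributes, or a
        :class:`pandas.DataFrame` with ``source``, ``target`` and ``weight``
        columns (case-insensitive).
    duplicates
        Policy for repeated undirected pairs: ``"error"`` (default) or
        ``"sum"`` (weights accumulated).
    drop_self_loops
        Silently discard self-loops instead of raising.

    Returns
    -------
    networkx.Graph
        A new graph with string node labels and validated weights.
    """
    if isinstance(data, pd.DataFrame):
        cols = {c.lower(): c for c in data.columns}
        missing = [c for c in ("source", "target", "weight") if c not in cols]
        if missing:
            raise ValueError(f"edge table missing columns: {missing}")
        triples = zip(data[cols["source"]], data[cols["target"]], data[cols["weight"]])
    elif isinstance(data, nx.Graph):
        if data.is_directed() or data.is_multigraph():
            raise ValueError("only simple undirected graphs are supported")
        triples = ((u, v, d.get("weight")) for u, v, d in data.edges(data=True))
    else:
        raise TypeError(f"cannot build a weighted network from {type(data).__name__}")

    if duplicates not in ("error", "sum"):
        raise ValueError("duplicates policy must be 'error' or 'sum'")

    g = nx.Graph()
    if isinstance(data, nx.Graph):
        # preserve isolated nodes and insertion order
        g.add_nodes_from(str(n) for n in data.nodes)
    for u, v, w in triples:
        u, v = str(u), str(v)
        if u == v:
            if drop_self_loops:
                g.add_node(u)
                continue
            raise ValueError(f"self-loop on node {u!r} (set drop_self_loops to ignore)")
        w = _check_weight(u, v, w)
        if g.has_edge(u, v):
            if duplicates == "error":
                raise ValueError(f"duplicate edge ({u!r}, {v!r})")
            g[u][v]["weight"] += w
        else:
            g.add_edge(u, v, weight=w)
    return g


def read_edgelist(
    path: str | PathLike,
    *,
    source: str = "source",
    target: str = "target",
    weight: str = "weight",
    duplicates: str = "error",
    drop_self_loops: bool = False,
    **csv_options,
) -> nx.Graph:
    """Read a weighted edge list from a CSV file with a header row."""
    csv_options.setdefault("float_precision", "round_trip")
    df = pd.read_csv(path, **csv_options)
    for col in (source, target, weight):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r} (have {list(df.columns)})")
    df = df.rename(columns={source: "source", target: "target", weight: "weight"})
    return as_weighted_network(
        df[["source", "target", "weight"]],
        duplicates=duplicates,
        drop_self_loops=drop_self_loops,
    )


def write_edgelist(net: nx.Graph, path: str | PathLike) -> None:
    """Write ``source,target,weight`` CSV (UTF-8, header included)."""
    rows = [(u, v, d["weight"]) for u, v, d in net.edges(data=True)]
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
        path, index=False
    )


def read_graphml(path: str | PathLike, **kwargs) -> nx.Graph:
    """Read a GraphML file and validate it as a weighted network.

    Extra edge/node attributes present in the file are preserved.
    """
    g = nx.read_graphml(path, **kwargs)
    if g.is_directed():
        raise ValueError(f"{path}: directed graphs are not supported")
    out = nx.Graph()
    for n, d in g.nodes(data=True):
        out.add_node(str(n), **d)
    for u, v, d in g.edges(data=True):
        u, v = str(u), str(v)
        if u == v:
            raise ValueError(f"{path}: self-loop on {u!r}")
        d = dict(d)
        d["weight"] = _check_weight(u, v, d.get("weight"))
        out.add_edge(u, v, **d)
    return out


def write_graphml(net: nx.Graph, path: str | PathLike) -> None:
    nx.write_graphml(net, path)


def require_integer_weights(net: nx.Graph, method: str) -> None:
    """Raise when any edge weight is not (numerically) an integer.

    Methods whose null model treats a weight as a count of unit edges call
    this at entry.
    """
    for u, v, d in net.edges(data=True):
        w = d["weight"]
        if abs(w - round(w)) > 1e-9:
            raise ValueError(
                f"{method} requires integer weights; edge ({u!r}, {v!r}) has w={w}"
            )
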