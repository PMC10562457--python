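"""Full-scale replication on the 2006 US air transportation network.

The dataset (382 airports, ~9700 weighted routes; weights are passenger
counts) is not bundled: download the edge list from the original data
repository (https://gitlab.liris.cnrs.fr/coregraphie/netbone, examples/data)
and save it as ``data/us_airports.csv`` with columns source,target,weight.

Run:

    python scripts/usair_replication.py data/us_airports.csv

Prints the structural property-table rows, the high-salience node fraction
at a 5% edge fraction, the weight-distribution KS statistics of the
statistical methods at α = 0.05, and the consensual statistical backbone
size.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import netspine as ns
from netspine.backbone import FilterSpec
from netspine.compare import Compare
from netspine.filters import boolean_filter, fraction_filter
from netspine.measures import edge_weights, node_fraction, weight_fraction


def replicate(path) -> dict:
    g = ns.read_edgelist(path, duplicates="sum")
    values: dict[str, float] = {
        "nodes": g.number_of_nodes(),
        "edges": g.number_of_edges(),
    }

    mst = boolean_filter(ns.maximum_spanning_tree(g))
    values["mst_weight_fraction"] = weight_fraction(g, mst)
    metric = boolean_filter(ns.metric_backbone(g))
    values["metric_weight_fraction"] = weight_fraction(g, metric)
    hb = boolean_filter(ns.h_backbone(g))
    values["h_backbone_node_fraction"] = node_fraction(g, hb)

    hss = ns.high_salience_skeleton(g)
    values["hss_node_fraction_at_edge_fraction_0.05"] = node_fraction(
        g, fraction_filter(hss, 0.05)
    )

    session = Compare(g)
    for method in (
        ns.disparity,
        ns.marginal_likelihood,
        lambda net: ns.noise_corrected(net, mode="pvalue"),
        ns.ecm_filter,
        ns.lans,
    ):
        session.add_backbone(method(g))
    ks = session.distribution_ks_statistic(edge_weights, FilterSpec("threshold", 0.05))
    values["ecm_weight_ks"] = float(
        ks.loc["Enhanced Configuration Model Filter", "KS statistic"]
    )
    cons = session.consensus(FilterSpec("threshold", 0.05), drop_isolates=True)
    values["consensus_nodes"] = cons.number_of_nodes()
    values["consensus_edges"] = cons.number_of_edges()
    return values


if __name__ == "__main__":
    csv = Path(sys.argv[1] if len(sys.argv) > 1 else "data/us_airports.csv")
    if not csv.exists():
        sys.exit(f"dataset not found: {csv} (see module docstring)")
    print(json.dumps(replicate(csv), indent=2))
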