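"""Transcription-regulatory network of the DEGs.

A precomputed TF->target table (e.g. derived offline from a motif
database) is restricted to the differentially expressed genes: an edge
survives when both the factor and its target are DEGs.  Core TFs are those
regulating strictly more than ``min_targets`` surviving targets, and a
focal-TF ego network extracts one regulator's direct neighbourhood.
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

__all__ = ["build_trn", "core_tfs", "ego_network"]

log = logging.getLogger(__name__)


def build_trn(
    deg_table: pd.DataFrame,
    tf_targets: dict[str, set[str]],
    require_tf_deg: bool = True,
) -> nx.DiGraph:
    """Directed TF->target network restricted to selected DEGs.

    By default the TF itself must be a DEG to appear (set
    ``require_tf_deg=False`` for exploratory networks with non-DEG
    regulators).  Node attributes: ``is_tf`` and the DEG ``direction``.
    """
    if "selected" in deg_table.columns:
        degs = set(deg_table.index[deg_table["selected"]])
    else:
        degs = set(deg_table.index)
    if not degs:
        raise ValueError("empty DEG set")

    net = nx.DiGraph(kind="trn")
    for tf, targets in tf_targets.items():
        if require_tf_deg and tf not in degs:
            continue
        kept = sorted(t for t in targets if t in degs and t != tf)
        if not kept:
            continue
        for target in kept:
            net.add_edge(tf, target)
        net.nodes[tf]["is_tf"] = True
    if net.number_of_nodes() == 0:
        log.warning("no TF-target edge survives the DEG restriction")
    for node in net.nodes:
        net.nodes[node].setdefault("is_tf", False)
        if node in deg_table.index:
            net.nodes[node]["direction"] = str(deg_table.loc[node, "direction"])
    log.info("TRN: %d nodes, %d edges, %d TFs", net.number_of_nodes(),
             net.number_of_edges(), sum(1 for v in net if net.nodes[v]["is_tf"]))
    return net


def core_tfs(net: nx.DiGraph, min_targets: int = 10) -> pd.DataFrame:
    """TFs with strictly more than ``min_targets`` targets, most first.

    Ties are broken by TF name; the result is invariant to edge order.
    """
    counts = [
        (tf, net.out_degree(tf))
        for tf in net.nodes
        if net.nodes[tf].get("is_tf") and net.out_degree(tf) > min_targets
    ]
    counts.sort(key=lambda item: (-item[1], item[0]))
    return pd.DataFrame(counts, columns=["tf", "n_targets"]).set_index("tf")


def ego_network(net: nx.DiGraph, focal: str) -> nx.DiGraph:
    """Focal gene plus its in/out neighbours and all edges among them."""
    if focal not in net:
        raise KeyError(f"focal gene {focal!r} not in the network")
    keep = {focal} | set(net.predecessors(focal)) | set(net.successors(focal))
    ego = net.subgraph(keep).copy()
    ego.nodes[focal]["focal"] = True
    return ego
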