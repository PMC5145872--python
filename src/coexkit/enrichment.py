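"""Gene-set overrepresentation, GO-Tree and pathway cross-talk networks.

Overrepresentation of a DEG list in annotated gene sets is scored with the
one-sided Fisher exact test (the upper hypergeometric tail of the 2x2
table overlap / DEG-only / term-only / neither).  Significant biological
process terms are arranged into a GO-Tree — the induced is_a sub-DAG that
connects every significant term upward, with the minimal scaffolding of
non-significant ancestors.  Significant pathway terms form a cross-talk
network in which two pathways are linked when they share DEGs (Jaccard
weight), or according to an explicit relation table when one is supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSet",
    "AnnotationBundle",
    "hypergeom_tail",
    "fisher_enrichment",
    "build_go_tree",
    "build_pathway_act_network",
]

log = logging.getLogger(__name__)


class GeneSet(NamedTuple):
    name: str
    category: str          # BP / MF / CC / pathway
    genes: frozenset[str]


@dataclass
class AnnotationBundle:
    """Gene sets, GO-like DAG and TF->target map consumed downstream.

    ``dag`` is a directed graph with is_a edges child -> parent and a
    ``namespace`` attribute per node.
    """

    gene_sets: dict[str, GeneSet]
    dag: nx.DiGraph
    tf_targets: dict[str, set[str]]

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.dag):
            raise ValueError("GO DAG contains a cycle")
        for term, gs in self.gene_sets.items():
            if not gs.genes:
                raise ValueError(f"gene set {term} is empty")

    @property
    def annotated_genes(self) -> set[str]:
        out: set[str] = set()
        for gs in self.gene_sets.values():
            out |= gs.genes
        return out

    def namespace_root(self, term: str) -> str | None:
        """The sink (no outgoing is_a edge) reachable from ``term``."""
        node = term
        seen = {node}
        while True:
            parents = sorted(self.dag.successors(node))
            if not parents:
                return node
            node = parents[0]
            if node in seen:   # defensive; DAG already validated
                return node
            seen.add(node)


def hypergeom_tail(overlap: int, n_background: int, n_term: int, n_deg: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(N=n_background, K=n_term, n=n_deg).

    This is the one-sided Fisher exact p-value for enrichment; the observed
    table is included in the tail, so overlap = 0 gives p = 1.
    """
    return float(stats.hypergeom.sf(overlap - 1, n_background, n_term, n_deg))


def fisher_enrichment(
    deg_genes: Iterable[str],
    bundle: AnnotationBundle,
    background: Iterable[str],
    p_thr: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher overrepresentation of DEGs in every gene set.

    Each term is intersected with the background before testing; terms with
    no background overlap are skipped.  BH FDR is computed within each
    category.  Rows are sorted by p (ties by term id).
    """
    deg = set(deg_genes)
    bg = set(background)
    if not deg:
        raise ValueError("empty DEG set")
    if not bg:
        raise ValueError("empty background")
    stray = deg - bg
    if stray:
        raise ValueError(f"DEGs outside the background: {sorted(stray)[:5]}")

    rows = []
    for term, gs in bundle.gene_sets.items():
        term_bg = gs.genes & bg
        if not term_bg:
            log.info("term %s has no overlap with the background; skipped", term)
            continue
        k = len(term_bg & deg)
        p = hypergeom_tail(k, len(bg), len(term_bg), len(deg))
        rows.append((term, gs.name, gs.category, k, len(term_bg), p))
    records = pd.DataFrame(
        rows, columns=["term", "name", "category", "count", "term_size", "p"]
    )
    records["fdr"] = np.nan
    for cat, idx in records.groupby("category").groups.items():
        records.loc[idx, "fdr"] = multipletests(records.loc[idx, "p"], method="fdr_bh")[1]
    records["significant"] = records["p"] < p_thr
    records = records.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
    return records


def _majority_direction(genes: set[str], deg_table: pd.DataFrame) -> str:
    sub = deg_table.loc[deg_table.index.intersection(list(genes))]
    if "selected" in sub.columns:
        sub = sub[sub["selected"]]
    n_up = int((sub["direction"] == "up").sum())
    n_down = int((sub["direction"] == "down").sum())
    if n_up > n_down:
        return "up"
    if n_down > n_up:
        return "down"
    return "mixed"


def _shortest_up_path(dag: nx.DiGraph, start: str, targets: set[str]) -> list[str] | None:
    """Shortest is_a path from ``start`` to the nearest node in ``targets``.

    BFS over parents; ties broken by exploring parents in sorted order.
    """
    from collections import deque

    prev: dict[str, str] = {}
    queue = deque([start])
    seen = {start}
    while queue:
        node = queue.popleft()
        for parent in sorted(dag.successors(node)):
            if parent in seen:
                continue
            prev[parent] = node
            if parent in targets:
                path = [parent]
                while path[-1] != start:
                    path.append(prev[path[-1]])
                return list(reversed(path))
            seen.add(parent)
            queue.append(parent)
    return None


def build_go_tree(
    records: pd.DataFrame,
    bundle: AnnotationBundle,
    deg_table: pd.DataFrame,
    p_thr: float = 0.01,
) -> nx.DiGraph:
    """GO-Tree over the significant biological-process terms.

    Nodes are BP terms with p < ``p_thr`` plus the minimal scaffolding of
    ancestors needed to connect them: each significant term is joined to its
    nearest significant ancestor through a shortest is_a path, and the
    namespace root is added only when more than one significant term would
    otherwise remain an apex.  Edges are the is_a edges of the induced
    sub-DAG.  Significant nodes are coloured up/down/mixed by the majority
    direction of their DEG overlap.
    """
    dag = bundle.dag
    bp = records[(records["category"] == "BP") & (records["p"] < p_thr)]
    graph = nx.DiGraph(kind="go_tree")
    deg_genes = set(deg_table.index[deg_table["selected"]]) if "selected" in deg_table.columns else set(deg_table.index)

    sig_terms = []
    for _, rec in bp.iterrows():
        term = rec["term"]
        if term not in dag:
            log.warning("significant term %s absent from the DAG; kept isolated", term)
            graph.add_node(term, significant=True, scaffold=False, p=float(rec["p"]),
                           name=rec["name"], color=_majority_direction(
                               set(bundle.gene_sets[term].genes) & deg_genes, deg_table))
            continue
        sig_terms.append(term)

    sig_set = set(sig_terms)
    nodes: set[str] = set(sig_set)
    apex: list[str] = []
    for term in sorted(sig_terms):
        path = _shortest_up_path(dag, term, sig_set - {term})
        if path is None:
            apex.append(term)
        else:
            nodes.update(path[:-1])  # intermediates are scaffold; endpoint already significant
            nodes.add(path[-1])
    if len(apex) > 1:
        for term in apex:
            root = bundle.namespace_root(term)
            path = _shortest_up_path(dag, term, {root}) if root != term else None
            if path:
                nodes.update(path)

    for node in sorted(nodes):
        sig = node in sig_set
        attrs = {"significant": sig, "scaffold": not sig,
                 "name": dag.nodes[node].get("name", node)}
        if sig:
            rec = bp[bp["term"] == node].iloc[0]
            attrs["p"] = float(rec["p"])
            attrs["color"] = _majority_direction(
                set(bundle.gene_sets[node].genes) & deg_genes, deg_table)
        else:
            attrs["color"] = "none"
        graph.add_node(node, **attrs)
    for child, parent in dag.edges():
        if child in nodes and parent in nodes:
            graph.add_edge(child, parent, kind="is_a", weight=1.0)
    return graph


def build_pathway_act_network(
    records: pd.DataFrame,
    bundle: AnnotationBundle,
    deg_genes: Iterable[str],
    deg_table: pd.DataFrame | None = None,
    p_thr: float = 0.05,
    link_table: Iterable[tuple[str, str]] | None = None,
) -> nx.Graph:
    """Cross-talk network over the significant pathway terms.

    Without a relation table, two significant pathways are linked when
    their DEG overlaps share at least one gene; the edge weight is the
    Jaccard index of the two DEG-overlap sets.  With a relation table, only
    its pairs restricted to significant pathways become edges.
    """
    deg = set(deg_genes)
    sig = records[(records["category"] == "pathway") & (records["p"] < p_thr)]
    graph = nx.Graph(kind="pathway_act")
    overlaps: dict[str, set[str]] = {}
    for _, rec in sig.iterrows():
        term = rec["term"]
        overlap = set(bundle.gene_sets[term].genes) & deg
        overlaps[term] = overlap
        color = _majority_direction(overlap, deg_table) if deg_table is not None else "none"
        graph.add_node(term, name=rec["name"], p=float(rec["p"]), color=color,
                       significant=True, scaffold=False)
    if link_table is not None:
        for a, b in link_table:
            if a in overlaps and b in overlaps and a != b:
                graph.add_edge(a, b, kind="crosstalk", weight=1.0)
        return graph
    terms = sorted(overlaps)
    for i, a in enumerate(terms):
        for b in terms[i + 1:]:
            shared = overlaps[a] & overlaps[b]
            if shared:
                union = overlaps[a] | overlaps[b]
                graph.add_edge(a, b, kind="crosstalk", weight=len(shared) / len(union))
    return graph
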