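"""Readers and writers for the pipeline's interchange formats.

Tables are TSV with a header; gene sets use GMT; the GO DAG is read from a
minimal OBO file (via obonet) or a 3-column child/parent/namespace TSV;
graphs are written as GraphML (round-trip safe) and SIF for Cytoscape.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import obonet
import pandas as pd

from .enrichment import AnnotationBundle, GeneSet
from .study import ExpressionStudy

__all__ = [
    "read_expression", "write_expression", "write_groups",
    "read_gmt", "write_gmt", "read_obo", "write_obo", "read_dag_tsv",
    "read_tf_table", "write_tf_table", "write_graph", "read_graph",
    "write_truth", "read_truth",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# expression


def read_expression(path, groups_path, case_label: str | None = None) -> ExpressionStudy:
    """Load an expression TSV (rows=genes) plus a two-column groups TSV.

    Duplicate gene ids are collapsed to their element-wise median (the
    probe-collapse convention); the count is logged.  Sample mismatches and
    non-numeric cells raise with the offending names.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    for col in frame.columns:
        if not pd.api.types.is_numeric_dtype(frame[col]):
            bad = frame.index[pd.to_numeric(frame[col], errors="coerce").isna()]
            raise ValueError(
                f"non-numeric value in column {col!r}, row(s) {bad.tolist()[:3]}"
            )
    if frame.isna().any().any():
        where = [(g, c) for g, c in zip(*np.where(frame.isna().to_numpy()))]
        raise ValueError(f"missing values at (row, col) positions {where[:3]}")
    n_dup = int(frame.index.duplicated().sum())
    if n_dup:
        log.info("collapsing %d duplicate gene id rows by median", n_dup)
        frame = frame.groupby(level=0, sort=False).median()

    groups_frame = pd.read_csv(groups_path, sep="\t", dtype=str)
    if groups_frame.shape[1] < 2:
        raise ValueError("groups file must have two columns: sample, group")
    groups = pd.Series(
        groups_frame.iloc[:, 1].values, index=groups_frame.iloc[:, 0].values
    )
    missing = [s for s in frame.columns if s not in groups.index]
    extra = [s for s in groups.index if s not in frame.columns]
    if missing:
        raise ValueError(f"samples without a group: {missing}")
    if extra:
        raise ValueError(f"groups file lists unknown samples: {extra}")
    return ExpressionStudy(frame, groups.loc[frame.columns], case_label)


def write_expression(study: ExpressionStudy, path) -> None:
    study.values.to_csv(path, sep="\t", index_label="gene")


def write_groups(study: ExpressionStudy, path) -> None:
    pd.DataFrame({"sample": study.sample_ids, "group": study.groups.values}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# gene sets / DAG / TF table


def read_gmt(path, category: str | None = None) -> dict[str, GeneSet]:
    """GMT: term <TAB> description <TAB> gene1 <TAB> gene2 ...

    The description field may carry ``category=...`` to tag the set; else
    ``category`` (or "BP") applies to every set in the file.
    """
    sets: dict[str, GeneSet] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs term, description, genes")
        term, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        cat = category or "BP"
        name = desc
        if "|category=" in desc:
            name, cat = desc.split("|category=", 1)
        sets[term] = GeneSet(name, cat, frozenset(genes))
    return sets


def write_gmt(gene_sets: dict[str, GeneSet], path) -> None:
    with open(path, "w") as fh:
        for term in sorted(gene_sets):
            gs = gene_sets[term]
            desc = f"{gs.name}|category={gs.category}"
            fh.write("\t".join([term, desc, *sorted(gs.genes)]) + "\n")


def write_obo(dag: nx.DiGraph, path) -> None:
    """Minimal OBO: one [Term] stanza per node with id/name/namespace/is_a."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        for node in sorted(dag.nodes):
            attrs = dag.nodes[node]
            fh.write("\n[Term]\n")
            fh.write(f"id: {node}\n")
            fh.write(f"name: {attrs.get('name', node)}\n")
            fh.write(f"namespace: {attrs.get('namespace', 'biological_process')}\n")
            for parent in sorted(dag.successors(node)):
                fh.write(f"is_a: {parent}\n")


def read_obo(path) -> nx.DiGraph:
    """Minimal OBO into a child->parent is_a DAG with name/namespace attrs."""
    multi = obonet.read_obo(path)
    dag = nx.DiGraph()
    for node, attrs in multi.nodes(data=True):
        dag.add_node(node, name=attrs.get("name", node),
                     namespace=attrs.get("namespace", "biological_process"))
    for child, parent, key in multi.edges(keys=True):
        if key == "is_a":
            dag.add_edge(child, parent, kind="is_a")
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError(f"{path}: is_a relation contains a cycle")
    return dag


def read_dag_tsv(path) -> nx.DiGraph:
    """3-column TSV child <TAB> parent <TAB> namespace."""
    frame = pd.read_csv(path, sep="\t", header=None,
                        names=["child", "parent", "namespace"], dtype=str)
    dag = nx.DiGraph()
    for _, row in frame.iterrows():
        dag.add_node(row["child"], namespace=row["namespace"],
                     name=dag.nodes.get(row["child"], {}).get("name", row["child"]))
        dag.add_node(row["parent"],
                     namespace=dag.nodes.get(row["parent"], {}).get("namespace", row["namespace"]),
                     name=dag.nodes.get(row["parent"], {}).get("name", row["parent"]))
        dag.add_edge(row["child"], row["parent"], kind="is_a")
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError(f"{path}: parent relation contains a cycle")
    return dag


def read_tf_table(path) -> dict[str, set[str]]:
    """Two-column TSV (TF, target); a header line 'tf<TAB>target' is allowed."""
    targets: dict[str, set[str]] = {}
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines, 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
        if lineno == 1 and parts[0].lower() in ("tf", "factor"):
            continue
        targets.setdefault(parts[0], set()).add(parts[1])
    return targets


def write_tf_table(tf_targets: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("tf\ttarget\n")
        for tf in sorted(tf_targets):
            for target in sorted(tf_targets[tf]):
                fh.write(f"{tf}\t{target}\n")


# ---------------------------------------------------------------------------
# graphs


def _sanitize(graph: nx.Graph) -> nx.Graph:
    out = graph.copy()
    def clean(attrs):
        for key, value in list(attrs.items()):
            if value is None:
                del attrs[key]
            elif isinstance(value, (np.floating, np.integer, np.bool_)):
                attrs[key] = value.item()
    clean(out.graph)
    for _, attrs in out.nodes(data=True):
        clean(attrs)
    for _, _, attrs in out.edges(data=True):
        clean(attrs)
    return out


def write_graph(graph: nx.Graph, path, fmt: str = "graphml") -> None:
    """GraphML (round-trip safe) or SIF (relation column = edge ``kind``)."""
    if graph is None:
        raise ValueError("graph is None")
    if fmt == "graphml":
        nx.write_graphml(_sanitize(graph), path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for a, b, attrs in graph.edges(data=True):
                rel = attrs.get("kind", "pd" if graph.is_directed() else "pp")
                fh.write(f"{a}\t{rel}\t{b}\n")
            for node in graph.nodes:
                if graph.degree(node) == 0:
                    fh.write(f"{node}\n")
    else:
        raise ValueError(f"unknown graph format {fmt!r}")


def read_graph(path) -> nx.Graph:
    return nx.read_graphml(path)


# ---------------------------------------------------------------------------
# truth JSON


def write_truth(truth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
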