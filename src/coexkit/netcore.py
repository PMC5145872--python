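"""Hard-threshold co-expression graphs and the differential k-core screen.

For each condition, genes are joined by an edge when their Pearson
correlation passes both a magnitude threshold (|r| >= r_thr) and a
two-sided significance threshold (p < p_thr, exact t transform on n-2 df).
The k-core of a gene — the largest k such that the gene survives iterated
pruning of all vertices with degree < k — summarises how deeply it is
embedded in the graph.  Genes whose coreness changes sharply between the
case and control graphs (|Dif_Kcore| above a strict threshold) are flagged
as key regulators.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .study import ExpressionStudy

__all__ = ["build_correlation_graph", "kcore_decomposition", "differential_kcore"]

log = logging.getLogger(__name__)


def correlation_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-value of a Pearson correlation via the t transform (n-2 df)."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, np.finfo(float).tiny))
    return 2.0 * stats.t.sf(np.abs(t), n - 2)


def build_correlation_graph(
    study: ExpressionStudy,
    condition: str,
    genes: list[str] | None = None,
    r_thr: float = 0.8,
    p_thr: float = 0.05,
) -> nx.Graph:
    """Pearson co-expression graph for one condition.

    Edge (i, j) iff |r_ij| >= r_thr and the correlation test p < p_thr;
    r and p are stored on the edge.  Zero-variance genes stay in the node
    set but receive no edges.
    """
    samples = study.samples_of(condition)
    if len(samples) < 4:
        raise ValueError(f"condition {condition!r} has {len(samples)} samples; need >= 4")
    if genes is None:
        genes = study.gene_ids
    sub = study.values.loc[genes, samples].to_numpy()
    n = sub.shape[1]

    graph = nx.Graph(condition=condition)
    graph.add_nodes_from(genes)
    sd = sub.std(axis=1)
    ok = sd > 0
    if (~ok).any():
        log.warning("%d zero-variance genes excluded from edges in %s",
                    int((~ok).sum()), condition)
    if ok.sum() < 2:
        return graph
    idx = np.where(ok)[0]
    r = np.corrcoef(sub[idx])
    p = correlation_pvalues(r, n)
    iu, ju = np.triu_indices(len(idx), k=1)
    keep = (np.abs(r[iu, ju]) >= r_thr) & (p[iu, ju] < p_thr)
    for a, b in zip(iu[keep], ju[keep]):
        graph.add_edge(genes[idx[a]], genes[idx[b]],
                       r=float(r[a, b]), p=float(p[a, b]))
    return graph


def kcore_decomposition(graph: nx.Graph) -> pd.DataFrame:
    """Coreness and degree per gene (standard peeling decomposition)."""
    if graph.number_of_nodes() == 0:
        return pd.DataFrame(columns=["degree", "kcore"])
    core = nx.core_number(graph)
    deg = dict(graph.degree())
    nodes = sorted(graph.nodes())
    return pd.DataFrame(
        {"degree": [deg[v] for v in nodes], "kcore": [core[v] for v in nodes]},
        index=pd.Index(nodes, name="gene"),
    )


def differential_kcore(
    case: pd.DataFrame,
    control: pd.DataFrame,
    threshold: int = 30,
) -> pd.DataFrame:
    """Coreness difference per gene; |dif_kcore| > threshold marks key regulators.

    Gene universes are unioned; a gene absent from one condition has
    coreness 0 there.  Rows are sorted by |dif_kcore| descending (ties by
    gene id).
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    genes = case.index.union(control.index)
    kc = case["kcore"].reindex(genes, fill_value=0).astype(int)
    kn = control["kcore"].reindex(genes, fill_value=0).astype(int)
    out = pd.DataFrame({"kcore_case": kc, "kcore_control": kn})
    out["dif_kcore"] = out["kcore_case"] - out["kcore_control"]
    out["key_regulator"] = out["dif_kcore"].abs() > threshold
    out = out.iloc[np.lexsort((out.index, -out["dif_kcore"].abs()))]
    out.index.name = "gene"
    return out
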