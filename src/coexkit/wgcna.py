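"""Weighted gene co-expression network analysis, implemented from scratch.

Pipeline: a soft threshold beta is chosen so the weighted network's degree
distribution approximates a scale-free law; the power adjacency

    S_mn = |(1 + cor(x_m, x_n)) / 2| ** beta

maps correlation into a [0, 1] edge weight (note: anticorrelated pairs map
near 0); the unsigned topological overlap

    omega_ij = (sum_{u != i,j} S_iu S_uj + S_ij) / (min(k_i, k_j) + 1 - S_ij)

combines direct adjacency with shared-neighbour agreement, and
d = 1 - omega is the clustering dissimilarity.  Modules come from cutting
an average-linkage dendrogram of d; each module is summarised by its
eigengene (first principal component of the standardised module
expression), and genes are scored by gene significance (GS, |cor| with the
case/control trait), module membership (MM, cor with a module eigengene)
and intramodular connectivity (IC, summed adjacency to co-members).  Hub
genes are the members with MM above a strict threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .study import ExpressionStudy

__all__ = [
    "WeightedNet",
    "SoftThresholdScan",
    "ModuleResult",
    "adjacency",
    "topological_overlap",
    "scale_free_fit",
    "pick_soft_threshold",
    "detect_modules",
    "module_eigengene",
    "score_genes",
    "select_hubs",
]

log = logging.getLogger(__name__)

# size-ranked module colour names; "gray" is reserved for unassigned genes
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "lightgreen", "lightyellow", "royalblue",
    "darkred", "darkgreen", "darkturquoise", "darkgrey", "orange",
]
GRAY = "gray"


def _as_frame(data) -> pd.DataFrame:
    if isinstance(data, ExpressionStudy):
        return data.values
    return data


@dataclass
class WeightedNet:
    """Power adjacency S, topological overlap omega and dissimilarity d."""

    genes: list[str]
    beta: float
    S: np.ndarray
    omega: np.ndarray | None = None
    d: np.ndarray | None = None

    @property
    def k(self) -> np.ndarray:
        """Weighted connectivity, diagonal excluded."""
        return self.S.sum(axis=1) - np.diag(self.S)

    def adjacency_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.S, index=self.genes, columns=self.genes)


@dataclass
class SoftThresholdScan:
    table: pd.DataFrame          # beta, r2, slope, mean_k, median_k
    chosen_beta: float
    reached_target: bool


@dataclass
class ModuleResult:
    """Module partition and the derived gene/module scores."""

    module_of_gene: pd.Series                      # gene -> colour label (incl. gray)
    me: pd.DataFrame | None = None                 # module x sample eigengenes
    gs: pd.Series | None = None                    # gene significance
    mm: pd.DataFrame | None = None                 # gene x module membership
    ic: pd.Series | None = None                    # intramodular connectivity
    ms: pd.Series | None = None                    # module significance (mean GS)
    module_trait: pd.DataFrame | None = None       # cor(ME, trait) + p per module

    @property
    def modules(self) -> list[str]:
        """Non-gray module labels, largest first."""
        counts = self.module_of_gene[self.module_of_gene != GRAY].value_counts()
        return counts.index.tolist()

    def genes_of(self, module: str) -> list[str]:
        return self.module_of_gene.index[self.module_of_gene == module].tolist()


# ---------------------------------------------------------------------------
# network construction


def _correlation(frame: pd.DataFrame) -> np.ndarray:
    x = frame.to_numpy(dtype=float)
    sd = x.std(axis=1)
    bad = sd == 0
    if bad.any():
        log.warning("%d zero-variance genes: correlations set to 0", int(bad.sum()))
    r = np.zeros((x.shape[0], x.shape[0]))
    ok = ~bad
    if ok.sum() >= 2:
        r[np.ix_(ok, ok)] = np.corrcoef(x[ok])
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def adjacency(data, beta: float) -> WeightedNet:
    """Power adjacency S_mn = |(1 + cor)/2|**beta; diagonal fixed to 1."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    frame = _as_frame(data)
    if frame.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    r = _correlation(frame)
    S = np.abs((1.0 + r) / 2.0) ** beta
    np.fill_diagonal(S, 1.0)
    return WeightedNet(genes=frame.index.tolist(), beta=float(beta), S=S)


def topological_overlap(net: WeightedNet) -> WeightedNet:
    """Unsigned TOM and its dissimilarity; fills ``net.omega`` and ``net.d``."""
    A = net.S.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    L = A @ A                       # (i,j): sum over shared neighbours u != i, j
    denom = np.minimum.outer(k, k) + 1.0 - A
    assert (denom > 0).all(), "TOM denominator must be positive for S in [0,1]"
    omega = (L + A) / denom
    np.fill_diagonal(omega, 1.0)
    omega = np.clip((omega + omega.T) / 2.0, 0.0, 1.0)
    net.omega = omega
    net.d = 1.0 - omega
    return net


# ---------------------------------------------------------------------------
# soft threshold


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free fit index of a connectivity vector.

    log10(k) is split into at most ``n_bins`` equal-width bins (empty bins
    dropped); log10(bin frequency) is regressed on log10(mean k per bin).
    Returns (r2 * sign(-slope), slope); degenerate inputs give (0, 0).
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 2 or np.ptp(k) == 0:
        return 0.0, 0.0
    logk = np.log10(k)
    edges = np.linspace(logk.min(), logk.max(), n_bins + 1)
    which = np.clip(np.digitize(logk, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.sum()))
    xs, ys = np.asarray(xs), np.asarray(ys)
    if len(xs) < 2 or np.ptp(xs) == 0:
        return 0.0, 0.0
    slope, intercept = np.polyfit(xs, ys, 1)
    ss_tot = float(((ys - ys.mean()) ** 2).sum())
    if ss_tot == 0:
        return 0.0, float(slope)
    ss_res = float(((ys - slope * xs - intercept) ** 2).sum())
    r2 = (1.0 - ss_res / ss_tot) * float(np.sign(-slope))
    return float(r2), float(slope)


def pick_soft_threshold(
    data,
    candidates: list[int] | None = None,
    target_r2: float = 0.8,
    n_bins: int = 10,
) -> SoftThresholdScan:
    """Scan candidate powers for approximate scale-free topology.

    The chosen beta is the smallest candidate whose signed fit index
    reaches ``target_r2``; if none does, the argmax is returned with
    ``reached_target=False`` and a warning.
    """
    frame = _as_frame(data)
    if frame.shape[0] < 20:
        raise ValueError("need >= 20 genes for a meaningful degree distribution")
    if candidates is None:
        candidates = list(range(1, 21))
    r = _correlation(frame)
    base = np.abs((1.0 + r) / 2.0)
    np.fill_diagonal(base, 0.0)
    rows = []
    for beta in candidates:
        k = (base ** beta).sum(axis=1)
        r2, slope = scale_free_fit(k, n_bins)
        if r2 == 0.0 and np.ptp(k) == 0:
            log.warning("all connectivities equal at beta=%s; fit defined as 0", beta)
        rows.append((beta, r2, slope, float(k.mean()), float(np.median(k))))
    table = pd.DataFrame(rows, columns=["beta", "r2", "slope", "mean_k", "median_k"])
    hit = table[table["r2"] >= target_r2]
    if len(hit):
        chosen = float(hit["beta"].iloc[0])
        reached = True
    else:
        chosen = float(table.loc[table["r2"].idxmax(), "beta"])
        reached = False
        log.warning("no candidate reached scale-free fit %.2f; falling back to "
                    "argmax r2 (beta=%g)", target_r2, chosen)
    return SoftThresholdScan(table=table, chosen_beta=chosen, reached_target=reached)


# ---------------------------------------------------------------------------
# module detection


def detect_modules(
    net: WeightedNet,
    cut_height: float = 0.99,
    min_module_size: int = 30,
    deep_split: int = 2,
) -> pd.Series:
    """Partition genes into co-expression modules by cutting the dendrogram.

    An average-linkage tree of d = 1 - omega is cut statically at
    ``cut_height``; with ``deep_split`` > 0 each resulting branch is then
    refined in two ways that approximate dynamic tree cutting:

    * **two-way splitting** — a merge whose children both hold at least
      ``min_module_size`` leaves joins two separable clusters (a pure
      module smaller than twice the minimum size can never satisfy this),
      so the branch is re-cut there, recursively;
    * **straggler trimming** — walking down from a branch top, side
      attachments smaller than ``0.125 * deep_split * min_module_size``
      genes are peeled off to gray; these are loosely attached genes that
      joined the branch just below the cut height.

    Clusters below ``min_module_size`` end up gray.  Surviving modules are
    labelled by descending size from a fixed colour palette.
    """
    if net.d is None:
        raise ValueError("run topological_overlap first")
    n = len(net.genes)
    labels = pd.Series(GRAY, index=net.genes, dtype=object)
    if min_module_size > n:
        log.warning("min_module_size %d exceeds gene count %d: everything gray",
                    min_module_size, n)
        return labels
    d = np.clip((net.d + net.d.T) / 2.0, 0.0, None)
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform(d, checks=False), method="average")
    root = to_tree(Z)

    branches = []
    stack = [root]
    while stack:
        node = stack.pop()
        if node.dist <= cut_height:
            branches.append(node)
        elif not node.is_leaf():
            stack.extend([node.left, node.right])

    trim_size = max(2, int(round(0.125 * deep_split * min_module_size)))
    modules: list[list[int]] = []

    def process(node) -> None:
        if node.count < min_module_size:
            return
        if deep_split > 0:
            while not node.is_leaf():
                left, right = node.left, node.right
                if min(left.count, right.count) >= min_module_size:
                    process(left)
                    process(right)
                    return
                big, small = (left, right) if left.count >= right.count else (right, left)
                if small.count < trim_size and big.count >= min_module_size:
                    node = big
                    continue
                break
        if node.count >= min_module_size:
            modules.append(node.pre_order(lambda leaf: leaf.id))

    for branch in branches:
        process(branch)

    # stable size ranking; ties broken by smallest member index
    modules.sort(key=lambda mem: (-len(mem), min(mem)))
    for rank, members in enumerate(modules):
        color = MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module{rank + 1}"
        labels.iloc[members] = color
    return labels


# ---------------------------------------------------------------------------
# eigengenes and scores


def module_eigengene(data, genes: list[str]) -> pd.Series:
    """First principal component of the standardised module expression.

    Unit norm over samples, sign-oriented so the mean correlation with the
    member genes is non-negative.
    """
    frame = _as_frame(data)
    if len(genes) < 2:
        raise ValueError("module must have >= 2 genes")
    sub = frame.loc[genes].to_numpy(dtype=float)
    sd = sub.std(axis=1)
    if (sd == 0).all():
        raise ValueError("module expression has rank 0 (all genes constant)")
    std = np.zeros_like(sub)
    ok = sd > 0
    std[ok] = (sub[ok] - sub[ok].mean(axis=1, keepdims=True)) / sd[ok, None]
    _, svals, vt = np.linalg.svd(std, full_matrices=False)
    if svals[0] == 0:
        raise ValueError("module expression has rank 0")
    me = vt[0]
    cors = [np.corrcoef(me, row)[0, 1] for row in std[ok]]
    if np.nanmean(cors) < 0:
        me = -me
    return pd.Series(me, index=frame.columns)


def _cor_with_vector(matrix: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation with one vector; constant rows give 0."""
    vc = v - v.mean()
    vs = np.sqrt((vc ** 2).sum())
    mc = matrix - matrix.mean(axis=1, keepdims=True)
    ms = np.sqrt((mc ** 2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (mc @ vc) / (ms * vs)
    return np.where(np.isfinite(r), r, 0.0)


def score_genes(
    study: ExpressionStudy,
    net: WeightedNet,
    partition: pd.Series,
    trait: pd.Series | None = None,
    signed_gs: bool = False,
) -> ModuleResult:
    """GS, MM, IC, MS and module-trait correlations for a partition.

    GS_g = |cor(x_g, trait)| (signed on request); MM is the correlation of
    every gene with every module eigengene; IC_g sums the adjacency of g to
    its module co-members; MS_m is the mean GS over module m (reported for
    gray too, but gray is never used for hub calling); the module-trait
    correlation carries a t-test p-value on n - 2 df.
    """
    if trait is None:
        trait = study.trait
    trait = trait.reindex(study.sample_ids).astype(float)
    if trait.nunique() < 2:
        raise ValueError("trait is constant")
    x = study.values.to_numpy(dtype=float)
    tvec = trait.to_numpy()
    n = len(tvec)

    gs_raw = _cor_with_vector(x, tvec)
    gs = pd.Series(gs_raw if signed_gs else np.abs(gs_raw), index=study.values.index)

    result = ModuleResult(module_of_gene=partition.copy())
    mes = {}
    for module in result.modules:
        mes[module] = module_eigengene(study.values, result.genes_of(module))
    me = pd.DataFrame(mes).T if mes else pd.DataFrame(columns=study.sample_ids)
    me = me.reindex(columns=study.sample_ids)

    mm = pd.DataFrame(
        {module: _cor_with_vector(x, me.loc[module].to_numpy()) for module in me.index},
        index=study.values.index,
    )

    gene_pos = {g: i for i, g in enumerate(net.genes)}
    ic = pd.Series(0.0, index=study.values.index)
    for module in partition.unique():
        members = [g for g in partition.index[partition == module] if g in gene_pos]
        idx = [gene_pos[g] for g in members]
        if len(idx) < 2:
            continue
        block = net.S[np.ix_(idx, idx)]
        ic.loc[members] = block.sum(axis=1) - np.diag(block)

    ms = gs.groupby(partition).mean()
    ms.name = "module_significance"

    rows = []
    for module in me.index:
        r = float(np.corrcoef(me.loc[module], tvec)[0, 1])
        tstat = r * np.sqrt((n - 2) / max(1.0 - r * r, np.finfo(float).tiny))
        p = float(2.0 * stats.t.sf(abs(tstat), n - 2))
        rows.append((module, r, p))
    module_trait = pd.DataFrame(rows, columns=["module", "cor", "p"]).set_index("module")

    result.me = me
    result.gs = gs
    result.mm = mm
    result.ic = ic
    result.ms = ms
    result.module_trait = module_trait
    return result


def _within_module_kcore(net: WeightedNet, members: list[str]) -> dict[str, int]:
    """Unweighted coreness inside one module.

    Edges join member pairs whose adjacency exceeds the module's median
    off-diagonal adjacency (a documented stand-in for an unspecified hard
    construction).
    """
    pos = {g: i for i, g in enumerate(net.genes)}
    idx = [pos[g] for g in members]
    block = net.S[np.ix_(idx, idx)]
    iu, ju = np.triu_indices(len(idx), k=1)
    if len(iu) == 0:
        return {g: 0 for g in members}
    med = float(np.median(block[iu, ju]))
    graph = nx.Graph()
    graph.add_nodes_from(members)
    for a, b in zip(iu, ju):
        if block[a, b] > med:
            graph.add_edge(members[a], members[b])
    return nx.core_number(graph)


def select_hubs(
    result: ModuleResult,
    net: WeightedNet,
    modules: list[str] | None = None,
    mm_thr: float = 0.9,
    ic_quantile: float = 0.0,
    deg_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Hub candidates of the chosen modules, sorted by MM descending.

    A gene is flagged as a hub when its membership in its own module
    strictly exceeds ``mm_thr`` (and, if ``ic_quantile`` > 0, its IC
    reaches that quantile within the module).  The table reports MM, IC and
    the within-module unweighted coreness for every member of the chosen
    modules; an empty module section is not an error.
    """
    if result.mm is None or result.ic is None:
        raise ValueError("run score_genes first")
    if modules is None:
        modules = result.modules
    rows = []
    for module in modules:
        members = result.genes_of(module)
        if not members:
            continue
        kcore = _within_module_kcore(net, members)
        ic_cut = result.ic.loc[members].quantile(ic_quantile) if ic_quantile > 0 else -np.inf
        for gene in members:
            mm = float(result.mm.loc[gene, module])
            ic = float(result.ic.loc[gene])
            hub = mm > mm_thr and ic >= ic_cut
            row = {"gene": gene, "module": module, "mm": mm, "ic": ic,
                   "kcore": int(kcore.get(gene, 0)), "gs": float(result.gs.loc[gene]),
                   "hub": bool(hub)}
            if deg_table is not None and gene in deg_table.index:
                row["log2fc"] = float(deg_table.loc[gene, "log2fc"])
                row["p"] = float(deg_table.loc[gene, "p"])
                row["fdr"] = float(deg_table.loc[gene, "fdr"])
                row["direction"] = deg_table.loc[gene, "direction"]
            rows.append(row)
    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values(["mm", "gene"], ascending=[False, True], kind="stable")
        table = table.set_index("gene")
    return table
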