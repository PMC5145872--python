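"""End-to-end orchestration of the analysis stages.

Order follows the analysis narrative: differential expression ->
enrichment (GO, GO-Tree, pathway cross-talk) -> per-condition hard
co-expression graphs with the differential k-core screen -> weighted
co-expression modules with hub calling -> transcription-regulatory
network.  Every stage writes its artifacts as it completes, and a summary
JSON (deterministic for a fixed config and inputs) records the headline
counts of each stage.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import dge, enrichment, io, netcore, trn, wgcna
from .config import PipelineConfig
from .study import ExpressionStudy

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            start = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:   # noqa: BLE001 - rewrap with stage name
                raise PipelineError(name, exc) from exc
            log.info("stage %s finished in %.1fs", name, time.perf_counter() - start)
            return out
        return inner
    return wrap


def run_pipeline(config: PipelineConfig, study: ExpressionStudy | None = None,
                 bundle=None) -> dict:
    """Run every stage and return the summary dict (also written as JSON).

    ``study`` and ``bundle`` may be passed directly (e.g. from the
    synthetic generator); otherwise they are loaded from the configured
    paths.  Identical config + inputs give a byte-identical summary file.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}

    if study is None:
        study = _stage("load")(io.read_expression)(
            config.expression, config.groups, config.case_label)
    if bundle is None and config.gene_sets:
        bundle = _stage("load")(_load_bundle)(config)

    # --- differential expression
    table, params = _stage("dge")(dge.moderated_t_test)(study)
    table = _stage("dge")(dge.select_degs)(table, config.p_thr, config.fc_thr)
    table.to_csv(outdir / "dge.tsv", sep="\t", index_label="gene")
    degs = table.index[table["selected"]].tolist()
    summary["dge"] = {
        "n_genes": study.n_genes, "n_deg": len(degs),
        "n_up": table.attrs["n_up"], "n_down": table.attrs["n_down"],
        "prior_df": params.d0 if params.d0 != float("inf") else "inf",
        "prior_var": round(params.s0_sq, 6),
    }
    if len(degs) >= 2:
        order = _stage("dge")(dge.cluster_for_heatmap)(study, degs)
        (outdir / "heatmap_gene_order.txt").write_text("\n".join(order.gene_order) + "\n")
        (outdir / "heatmap_sample_order.txt").write_text("\n".join(order.sample_order) + "\n")

    # --- enrichment
    if bundle is not None and degs:
        background = sorted(set(study.gene_ids) & bundle.annotated_genes)
        deg_bg = [g for g in degs if g in set(background)]
        if deg_bg:
            records = _stage("enrichment")(enrichment.fisher_enrichment)(
                deg_bg, bundle, background, config.enrich_p)
            records.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            go_tree = _stage("enrichment")(enrichment.build_go_tree)(
                records, bundle, table, config.gotree_p)
            io.write_graph(go_tree, outdir / "go_tree.graphml")
            io.write_graph(go_tree, outdir / "go_tree.sif", fmt="sif")
            links = None
            if config.pathway_links:
                link_frame = pd.read_csv(config.pathway_links, sep="\t", dtype=str)
                links = list(link_frame.itertuples(index=False, name=None))
            path_net = _stage("enrichment")(enrichment.build_pathway_act_network)(
                records, bundle, deg_bg, table, config.pathway_p, links)
            io.write_graph(path_net, outdir / "pathway_act.graphml")
            io.write_graph(path_net, outdir / "pathway_act.sif", fmt="sif")
            summary["enrichment"] = {
                "n_background": len(background),
                "n_terms_tested": int(len(records)),
                "n_significant": int(records["significant"].sum()),
                "go_tree_nodes": go_tree.number_of_nodes(),
                "go_tree_edges": go_tree.number_of_edges(),
                "pathway_net_nodes": path_net.number_of_nodes(),
                "pathway_net_edges": path_net.number_of_edges(),
            }

    # --- per-condition co-expression + differential k-core
    if len(degs) >= 2:
        coexp_genes = degs
    else:
        log.warning("fewer than 2 DEGs; co-expression stages use all genes")
        coexp_genes = study.gene_ids
    kcores = {}
    for label in (study.case_label, study.control_label):
        graph = _stage("netcore")(netcore.build_correlation_graph)(
            study, label, coexp_genes, config.r_thr, config.coexp_p)
        io.write_graph(graph, outdir / f"coexp_{label}.graphml")
        kcores[label] = _stage("netcore")(netcore.kcore_decomposition)(graph)
    dif = _stage("netcore")(netcore.differential_kcore)(
        kcores[study.case_label], kcores[study.control_label], config.dif_kcore_thr)
    dif.to_csv(outdir / "dif_kcore.tsv", sep="\t")
    summary["netcore"] = {
        "n_nodes": int(len(dif)),
        "n_key_regulators": int(dif["key_regulator"].sum()),
        "max_abs_dif_kcore": int(dif["dif_kcore"].abs().max()) if len(dif) else 0,
    }

    # --- weighted network + modules
    min_for_wgcna = max(2 * config.min_module_size, 20)
    if len(coexp_genes) >= min_for_wgcna:
        wgcna_genes = coexp_genes
    else:
        log.warning("too few DEGs for module detection; using all genes")
        wgcna_genes = study.gene_ids
    wstudy = study.subset_genes(wgcna_genes)
    scan = _stage("wgcna")(wgcna.pick_soft_threshold)(
        wstudy, config.beta_candidates, config.target_r2)
    scan.table.to_csv(outdir / "soft_threshold_scan.tsv", sep="\t", index=False)
    net = _stage("wgcna")(wgcna.adjacency)(wstudy, scan.chosen_beta)
    net = _stage("wgcna")(wgcna.topological_overlap)(net)
    partition = _stage("wgcna")(wgcna.detect_modules)(
        net, config.cut_height, config.min_module_size, config.deep_split)
    partition.rename("module").to_csv(outdir / "modules.tsv", sep="\t", index_label="gene")
    scores = _stage("wgcna")(wgcna.score_genes)(wstudy, net, partition)
    if scores.me is not None and len(scores.me):
        scores.me.to_csv(outdir / "eigengenes.tsv", sep="\t", index_label="module")
    pd.DataFrame({"module": partition, "gs": scores.gs,
                  "ic": scores.ic}).join(scores.mm.add_prefix("mm_")).to_csv(
        outdir / "gene_scores.tsv", sep="\t", index_label="gene")
    scores.module_trait.to_csv(outdir / "module_trait.tsv", sep="\t")
    trait_modules = scores.module_trait.index[scores.module_trait["p"] < 0.05].tolist()
    if not trait_modules and len(scores.module_trait):
        trait_modules = [scores.module_trait["cor"].abs().idxmax()]
    hubs = _stage("wgcna")(wgcna.select_hubs)(
        scores, net, trait_modules, config.mm_thr, deg_table=table)
    if len(hubs):
        hubs.to_csv(outdir / "hub_genes.tsv", sep="\t")
    module_sizes = partition.value_counts().to_dict()
    summary["wgcna"] = {
        "chosen_beta": scan.chosen_beta,
        "reached_target_r2": scan.reached_target,
        "n_modules": len(scores.modules),
        "module_sizes": {k: int(v) for k, v in sorted(module_sizes.items())},
        "trait_modules": trait_modules,
        "hub_genes": sorted(hubs.index[hubs["hub"]].tolist()) if len(hubs) else [],
    }

    # --- transcription-regulatory network
    if bundle is not None and degs:
        net_trn = _stage("trn")(trn.build_trn)(table, bundle.tf_targets)
        io.write_graph(net_trn, outdir / "trn.graphml")
        io.write_graph(net_trn, outdir / "trn.sif", fmt="sif")
        core = _stage("trn")(trn.core_tfs)(net_trn, config.min_targets)
        core.to_csv(outdir / "core_tfs.tsv", sep="\t")
        summary["trn"] = {
            "n_nodes": net_trn.number_of_nodes(),
            "n_edges": net_trn.number_of_edges(),
            "core_tfs": core.index.tolist(),
        }
        if config.focal_tf and config.focal_tf in net_trn:
            ego = _stage("trn")(trn.ego_network)(net_trn, config.focal_tf)
            io.write_graph(ego, outdir / f"trn_ego_{config.focal_tf}.graphml")
            summary["trn"]["ego_nodes"] = ego.number_of_nodes()

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _load_bundle(config: PipelineConfig):
    gene_sets = io.read_gmt(config.gene_sets)
    if config.go_dag.endswith(".obo"):
        dag = io.read_obo(config.go_dag)
    else:
        dag = io.read_dag_tsv(config.go_dag)
    tf_targets = io.read_tf_table(config.tf_targets) if config.tf_targets else {}
    return enrichment.AnnotationBundle(gene_sets=gene_sets, dag=dag, tf_targets=tf_targets)
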