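"""Synthetic two-condition expression studies with planted structure.

The generator emulates a peripheral-blood microarray case/control design
(two sample groups, a few hundred genes, log2-scale intensities) with three
kinds of planted, recoverable truth:

* **co-expression modules** — each module m has one latent per-sample factor
  f_m ~ N(0, 1); member gene g follows  x_g = mu_g + lambda_g * f_m + eps,
  eps ~ N(0, noise_sd^2), so any two members are correlated through f_m;
* **differentially expressed genes** — an additive log2 shift of
  ``+/- de_effect`` in the case group, so a fold-change threshold translates
  exactly (FC > c  <=>  |delta log2| > log2 c);
* **hub genes** — per module, one gene carries the top loading of
  ``loading_range`` while the remaining members draw from the lower part of
  the range, making the hub's identity unambiguous.

Background genes are i.i.d. noise so the unassigned ("gray") pool has a
crisp truth.  A matching toy annotation bundle (GO-like DAG, gene sets,
TF->target table) is derived from the same truth so that the enrichment and
regulatory-network stages are verifiable end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import AnnotationBundle, GeneSet
from .study import ExpressionStudy

__all__ = ["SimConfig", "SyntheticTruth", "generate_expression", "generate_annotations"]

BACKGROUND = "background"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the package's reference design: 5 modules of 40
    genes plus 400 background genes, 26 case + 26 control samples, factor
    loadings in [0.7, 1.0], unit log2 noise, and a coherent +/-1 log2 group
    shift planted in the first module.
    """

    n_genes: int = 600
    n_samples_per_group: tuple[int, int] = (26, 26)
    n_modules: int = 5
    module_size: int = 40
    loading_range: tuple[float, float] = (0.7, 1.0)
    hub_gap: float = 0.5
    de_fraction: float = 0.1
    de_effect: float = 1.0
    de_module: int | None = 0
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.module_size < 3:
            raise ValueError("module_size < 3: modules would be undetectable")
        if min(self.n_samples_per_group) < 3:
            raise ValueError("need >= 3 samples per group")
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("n_modules * module_size exceeds n_genes")
        lo, hi = self.loading_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("loading_range must lie in (0, 1] with lo <= hi")
        if not 0 <= self.hub_gap < 1:
            raise ValueError("hub_gap must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.de_effect < 0:
            raise ValueError("de_effect must be non-negative")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.de_module is not None and not 0 <= self.de_module < self.n_modules:
            raise ValueError("de_module out of range")


@dataclass
class SyntheticTruth:
    """Ground truth of one generated study."""

    module_of_gene: pd.Series          # gene -> "M1".."Mk" or "background"
    de_effect_of_gene: pd.Series       # signed log2 shift; DE genes only
    hub_of_module: dict[str, str]      # module label -> gene id
    trait: pd.Series                   # sample -> 0/1 (1 = case)
    latent_factors: pd.DataFrame       # module label x sample
    loadings: pd.Series | None = None  # gene -> factor loading (module genes)

    def __post_init__(self) -> None:
        for mod, hub in self.hub_of_module.items():
            if self.module_of_gene.get(hub) != mod:
                raise ValueError(f"planted hub {hub} not in its module {mod}")

    def module_genes(self, module: str) -> list[str]:
        return self.module_of_gene.index[self.module_of_gene == module].tolist()

    def to_dict(self) -> dict:
        return {
            "module_of_gene": self.module_of_gene.to_dict(),
            "de_effect_of_gene": self.de_effect_of_gene.to_dict(),
            "hub_of_module": dict(self.hub_of_module),
            "trait": {k: int(v) for k, v in self.trait.items()},
            "loadings": self.loadings.to_dict() if self.loadings is not None else {},
        }


def _module_label(m: int) -> str:
    return f"M{m + 1}"


def generate_expression(config: SimConfig) -> tuple[ExpressionStudy, SyntheticTruth]:
    """Draw one synthetic study and its ground truth.

    Same config (including seed) produces bit-identical output; all
    randomness flows from one seeded generator.
    """
    rng = np.random.default_rng(config.seed)
    n_case, n_ctrl = config.n_samples_per_group
    n = n_case + n_ctrl
    width = len(str(config.n_genes))
    genes = [f"G{i + 1:0{width}d}" for i in range(config.n_genes)]
    samples = [f"S{j + 1:02d}" for j in range(n)]
    groups = pd.Series(["case"] * n_case + ["control"] * n_ctrl, index=samples)
    trait = (groups == "case").astype(int)

    mu = rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)
    x = mu[:, None] + rng.normal(0.0, config.noise_sd, (config.n_genes, n))

    lo, hi = config.loading_range
    member_hi = hi - config.hub_gap * (hi - lo)
    module_of_gene = pd.Series(BACKGROUND, index=genes, dtype=object)
    hub_of_module: dict[str, str] = {}
    factors = {}
    loadings = pd.Series(dtype=float)
    for m in range(config.n_modules):
        label = _module_label(m)
        idx = np.arange(m * config.module_size, (m + 1) * config.module_size)
        lam = rng.uniform(lo, member_hi, config.module_size)
        hub_pos = int(rng.integers(config.module_size))
        lam[hub_pos] = hi
        f = rng.standard_normal(n)
        x[idx] += lam[:, None] * f[None, :]
        module_of_gene.iloc[idx] = label
        hub_of_module[label] = genes[idx[hub_pos]]
        factors[label] = f
        loadings = pd.concat([loadings, pd.Series(lam, index=[genes[i] for i in idx])])

    background = module_of_gene.index[module_of_gene == BACKGROUND].tolist()
    n_de = int(round(config.de_fraction * config.n_genes))
    de_genes: list[str] = []
    de_signs: list[float] = []
    if config.de_module is not None:
        label = _module_label(config.de_module)
        mod_genes = module_of_gene.index[module_of_gene == label].tolist()
        sign = 1.0 if rng.random() < 0.5 else -1.0
        de_genes += mod_genes
        de_signs += [sign] * len(mod_genes)
    extra = max(0, n_de - len(de_genes))
    if extra > 0 and background:
        extra = min(extra, len(background))
        picks = rng.choice(len(background), size=extra, replace=False)
        for p in sorted(picks):
            de_genes.append(background[p])
            de_signs.append(1.0 if rng.random() < 0.5 else -1.0)

    de_effects = pd.Series(
        [s * config.de_effect for s in de_signs], index=de_genes, dtype=float
    )
    if config.de_effect > 0 and len(de_genes) > 0:
        rows = [genes.index(g) for g in de_genes]
        x[np.array(rows)[:, None], np.where(trait.values == 1)[0][None, :]] += (
            de_effects.values[:, None]
        )

    values = pd.DataFrame(x, index=genes, columns=samples)
    study = ExpressionStudy(values, groups)
    truth = SyntheticTruth(
        module_of_gene=module_of_gene,
        de_effect_of_gene=de_effects,
        hub_of_module=hub_of_module,
        trait=trait,
        latent_factors=pd.DataFrame(factors, index=samples).T,
        loadings=loadings,
    )
    return study, truth


# ---------------------------------------------------------------------------
# annotations


def generate_annotations(
    truth: SyntheticTruth,
    config: SimConfig,
    term_coverage: float = 0.9,
    n_distractor_sets: int = 5,
) -> AnnotationBundle:
    """Toy annotation bundle matched to a generated truth.

    Emits (a) a rooted GO-like DAG of >= 3 levels; (b) one designated BP
    term and one designated pathway term per planted module, each holding
    ``term_coverage`` of the module's genes plus random background genes;
    (c) a TF->target table in which each module's planted hub targets every
    other member of its module.
    """
    rng = np.random.default_rng([config.seed, 1701])
    genes = truth.module_of_gene.index.tolist()
    background = truth.module_of_gene.index[truth.module_of_gene == BACKGROUND].tolist()
    modules = sorted(truth.hub_of_module)

    dag = nx.DiGraph()
    root = "GO:0000001"
    dag.add_node(root, name="biological_process", namespace="biological_process")
    mids = []
    for i in range(max(2, math.ceil(len(modules) / 3))):
        mid = f"GO:00000{i + 2:02d}"
        dag.add_node(mid, name=f"process group {i + 1}", namespace="biological_process")
        dag.add_edge(mid, root, kind="is_a")
        mids.append(mid)

    gene_sets: dict[str, GeneSet] = {}
    for i, mod in enumerate(modules):
        members = truth.module_genes(mod)
        n_keep = math.ceil(term_coverage * len(members))
        keep = [members[j] for j in sorted(rng.choice(len(members), n_keep, replace=False))]
        pad = [background[j] for j in sorted(rng.choice(len(background), min(10, len(background)), replace=False))]
        term = f"GO:00001{i + 1:02d}"
        dag.add_node(term, name=f"{mod} response", namespace="biological_process")
        dag.add_edge(term, mids[i % len(mids)], kind="is_a")
        gene_sets[term] = GeneSet(f"{mod} response", "BP", frozenset(keep + pad))
        pw = f"PW:000{i + 1:02d}"
        gene_sets[pw] = GeneSet(f"{mod} signalling pathway", "pathway", frozenset(keep + pad))

    for i in range(n_distractor_sets):
        size = min(30, len(background))
        draw = [background[j] for j in sorted(rng.choice(len(background), size, replace=False))]
        term = f"GO:00002{i + 1:02d}"
        dag.add_node(term, name=f"unrelated process {i + 1}", namespace="biological_process")
        dag.add_edge(term, mids[i % len(mids)], kind="is_a")
        gene_sets[term] = GeneSet(f"unrelated process {i + 1}", "BP", frozenset(draw))
        pw = f"PW:001{i + 1:02d}"
        gene_sets[pw] = GeneSet(f"unrelated pathway {i + 1}", "pathway", frozenset(draw))

    tf_targets: dict[str, set[str]] = {}
    for mod in modules:
        hub = truth.hub_of_module[mod]
        tf_targets[hub] = {g for g in truth.module_genes(mod) if g != hub}
    # a couple of background regulators so the table is not purely planted
    n_extra_tfs = min(2, max(0, len(background) - 10))
    for i in range(n_extra_tfs):
        tf = background[i]
        pool = [g for g in genes if g != tf]
        draw = rng.choice(len(pool), min(8, len(pool)), replace=False)
        tf_targets.setdefault(tf, set()).update(pool[j] for j in sorted(draw))

    return AnnotationBundle(gene_sets=gene_sets, dag=dag, tf_targets=tf_targets)
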