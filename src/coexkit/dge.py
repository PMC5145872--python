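"""Moderated two-group differential expression and heatmap clustering.

The test statistic is the empirical-Bayes moderated t: per-gene pooled
variances s_g^2 (d_g = n1 + n2 - 2 residual df) are shrunk toward a prior
variance s0^2 whose weight d0 (prior df) is estimated by moment matching of
log s_g^2 against a scaled-F model, via digamma/trigamma inversion.  The
moderated statistic

    t_g = log2FC_g / sqrt( s~_g^2 * (1/n1 + 1/n2) ),
    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),

is referred to a t distribution on d0 + d_g df (standard normal when
d0 = inf).  Selection follows the fold-change + raw-p rule customary in
two-colour/affymetrix blood studies: FC > 1.2 and P < 0.05 by default, with
Benjamini-Hochberg FDR reported alongside.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .study import ExpressionStudy

__all__ = [
    "EBayesParams",
    "moderated_t_test",
    "select_degs",
    "cluster_for_heatmap",
    "correlation_distance",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EBayesParams:
    """Estimated empirical-Bayes hyperparameters."""

    d0: float          # prior degrees of freedom (may be inf)
    s0_sq: float       # prior variance
    d_g: int           # residual df per gene (n1 + n2 - 2)

    @property
    def moderation_off(self) -> bool:
        return self.d0 == 0


def _trigamma(x):
    return polygamma(1, x)


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 80) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = _trigamma(x)
        step = tri * (1.0 - tri / y) / polygamma(2, x)
        x += step
        if abs(step) < tol * x:
            break
    return float(x)


def _fit_prior(s2: np.ndarray, d_g: int) -> tuple[float, float]:
    """Moment-match (d0, s0^2) from the spread of log sample variances.

    log s_g^2 is modelled as log(s0^2 * F(d_g, d0)); the excess of
    var(log s_g^2) over trigamma(d_g/2) identifies d0, and the mean
    identifies s0^2.  Zero variances carry no information and are excluded.
    """
    z = np.log(s2[s2 > 0])
    if z.size < 2:
        raise ValueError("cannot estimate prior variance: fewer than 2 genes with positive variance")
    e = z - digamma(d_g / 2.0) + np.log(d_g / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(_trigamma(d_g / 2.0))
    if not np.isfinite(evar):
        raise FloatingPointError("moment matching produced a non-finite spread")
    if evar > 0:
        half_d0 = _trigamma_inverse(evar)
        d0 = 2.0 * half_d0
        s0_sq = float(np.exp(emean + digamma(half_d0) - np.log(half_d0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return d0, s0_sq


def moderated_t_test(
    study: ExpressionStudy,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> tuple[pd.DataFrame, EBayesParams]:
    """Moderated t statistics for case vs. control.

    Parameters
    ----------
    study : ExpressionStudy
    prior_df, prior_var : float, optional
        Override the estimated hyperparameters (``prior_df=0`` disables
        moderation and reproduces the ordinary pooled two-sample t).

    Returns
    -------
    (table, params)
        ``table`` indexed by gene with columns log2fc, t, p, fdr,
        direction; ``params`` holds (d0, s0^2, d_g).
    """
    case = study.matrix(study.case_label).to_numpy()
    ctrl = study.matrix(study.control_label).to_numpy()
    n1, n2 = case.shape[1], ctrl.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need >= 2 samples per group, got {n1} and {n2}")
    d_g = n1 + n2 - 2

    log2fc = case.mean(axis=1) - ctrl.mean(axis=1)
    ss = case.var(axis=1, ddof=1) * (n1 - 1) + ctrl.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / d_g

    if prior_df is not None:
        d0 = float(prior_df)
        if d0 > 0:
            s0_sq = float(prior_var) if prior_var is not None else _fit_prior(s2, d_g)[1]
        else:
            s0_sq = float(prior_var) if prior_var is not None else float(np.mean(s2[s2 > 0])) if np.any(s2 > 0) else 1.0
    else:
        try:
            d0, s0_sq = _fit_prior(s2, d_g)
        except FloatingPointError:
            warnings.warn(
                "prior df estimate non-finite; falling back to the ordinary t statistic",
                RuntimeWarning,
                stacklevel=2,
            )
            d0, s0_sq = 0.0, float(np.mean(s2[s2 > 0])) if np.any(s2 > 0) else 1.0

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = float(d_g)
    else:
        s2_post = (d0 * s0_sq + d_g * s2) / (d0 + d_g)
        df_total = d0 + d_g

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), np.where(log2fc == 0, 0.0, np.sign(log2fc) * np.inf))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    fdr = multipletests(p, method="fdr_bh")[1]

    direction = np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "none"))
    table = pd.DataFrame(
        {"log2fc": log2fc, "t": t, "p": p, "fdr": fdr, "direction": direction},
        index=study.values.index,
    )
    return table, EBayesParams(d0=float(d0), s0_sq=float(s0_sq), d_g=d_g)


def select_degs(table: pd.DataFrame, p_thr: float = 0.05, fc_thr: float = 1.2) -> pd.DataFrame:
    """Flag differentially expressed genes: p < p_thr and FC > fc_thr.

    The fold-change rule is applied on the anti-logged scale,
    ``2**|log2fc| > fc_thr`` (strict), so FC = fc_thr exactly does not pass.
    """
    if not 0 < p_thr < 1:
        raise ValueError(f"p_thr must lie in (0, 1), got {p_thr}")
    if fc_thr <= 1:
        raise ValueError(f"fc_thr must exceed 1, got {fc_thr}")
    out = table.copy()
    out["selected"] = (out["p"] < p_thr) & (np.exp2(np.abs(out["log2fc"])) > fc_thr)
    n_up = int(((out["direction"] == "up") & out["selected"]).sum())
    n_down = int(((out["direction"] == "down") & out["selected"]).sum())
    out.attrs["n_up"] = n_up
    out.attrs["n_down"] = n_down
    log.info("selected %d DEGs (%d up, %d down) at p<%g, FC>%g",
             n_up + n_down, n_up, n_down, p_thr, fc_thr)
    return out


def correlation_distance(matrix: np.ndarray) -> np.ndarray:
    """1 - Pearson distance between rows; zero-variance rows sit at distance 1."""
    matrix = np.asarray(matrix, dtype=float)
    sd = matrix.std(axis=1)
    ok = sd > 0
    dist = np.ones((matrix.shape[0], matrix.shape[0]))
    if ok.sum() >= 2:
        r = np.corrcoef(matrix[ok])
        dist[np.ix_(ok, ok)] = 1.0 - r
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    return dist


@dataclass
class HeatmapOrder:
    gene_order: list[str]
    sample_order: list[str]
    gene_linkage: np.ndarray
    sample_linkage: np.ndarray


def cluster_for_heatmap(study: ExpressionStudy, genes: list[str]) -> HeatmapOrder:
    """Average-linkage orderings of genes and samples for a heatmap.

    Distance is 1 - Pearson correlation (gene-gene across samples;
    sample-sample across the chosen genes); leaf order is deterministic.
    """
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to cluster")
    sub = study.values.loc[genes]
    gd = correlation_distance(sub.to_numpy())
    gz = linkage(squareform(gd, checks=False), method="average")
    sd = correlation_distance(sub.to_numpy().T)
    sz = linkage(squareform(sd, checks=False), method="average")
    return HeatmapOrder(
        gene_order=[genes[i] for i in leaves_list(gz)],
        sample_order=[sub.columns[i] for i in leaves_list(sz)],
        gene_linkage=gz,
        sample_linkage=sz,
    )
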