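"""Independent brute-force oracles, written before and apart from the
implementations they check.  Each one is a literal transcription of the
defining equations or an exhaustive procedure; none shares code with the
package.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import digamma, polygamma


# ---------------------------------------------------------------------------
# empirical-Bayes moderated t (step-by-step moment matching)


def ebayes_oracle(case: np.ndarray, ctrl: np.ndarray):
    """Recompute (d0, s0^2, t, p) directly from the moment-matching equations."""
    n1, n2 = case.shape[1], ctrl.shape[1]
    d = n1 + n2 - 2
    fc = case.mean(1) - ctrl.mean(1)
    s2 = (case.var(1, ddof=1) * (n1 - 1) + ctrl.var(1, ddof=1) * (n2 - 1)) / d

    z = np.log(s2[s2 > 0])
    e = z - digamma(d / 2) + math.log(d / 2)
    emean = e.mean()
    evar = e.var(ddof=1) - polygamma(1, d / 2)
    if evar > 0:
        # Newton solve trigamma(x) = evar
        x = 0.5 + 1.0 / evar
        for _ in range(100):
            f = polygamma(1, x) - evar
            x_new = x - f / polygamma(2, x)
            if abs(x_new - x) < 1e-12 * abs(x):
                x = x_new
                break
            x = x_new
        d0 = 2 * x
        s0_sq = math.exp(emean + digamma(x) - math.log(x))
    else:
        d0 = math.inf
        s0_sq = math.exp(emean)

    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df = math.inf
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df = d0 + d
    t = fc / np.sqrt(s2_post * (1 / n1 + 1 / n2))
    from scipy import stats
    if math.isinf(df):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df)
    return d0, s0_sq, t, p


# ---------------------------------------------------------------------------
# Benjamini-Hochberg step-up


def bh_oracle(pvals):
    """Textbook step-up adjusted p-values: p_(i) * m / i, cummin from the top."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


# ---------------------------------------------------------------------------
# hypergeometric upper tail by exact integer enumeration


def hypergeom_tail_oracle(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), summed with exact integers."""
    lo = max(k, 0, n + K - N)
    hi = min(K, n)
    total = math.comb(N, n)
    acc = 0
    for i in range(lo, hi + 1):
        acc += math.comb(K, i) * math.comb(N - K, n - i)
    return acc / total


# ---------------------------------------------------------------------------
# unsigned TOM, naive triple loop


def tom_oracle(S: np.ndarray) -> np.ndarray:
    n = S.shape[0]
    k = np.array([sum(S[i, u] for u in range(n) if u != i) for i in range(n)])
    omega = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            num = sum(S[i, u] * S[u, j] for u in range(n) if u != i and u != j)
            omega[i, j] = (num + S[i, j]) / (min(k[i], k[j]) + 1 - S[i, j])
    return omega


# ---------------------------------------------------------------------------
# k-core by exhaustive pruning at every k


def kcore_oracle(nodes, edges):
    """Coreness per node: largest k at which the node survives pruning."""
    adj = {v: set() for v in nodes}
    for a, b in edges:
        if a != b:
            adj[a].add(b)
            adj[b].add(a)
    core = {v: 0 for v in nodes}
    max_deg = max((len(adj[v]) for v in nodes), default=0)
    for k in range(1, max_deg + 1):
        alive = set(nodes)
        changed = True
        while changed:
            changed = False
            for v in list(alive):
                deg = len(adj[v] & alive)
                if deg < k:
                    alive.discard(v)
                    changed = True
        for v in alive:
            core[v] = k
    return core


# ---------------------------------------------------------------------------
# average-linkage agglomeration, O(n^3) full rescan


def average_linkage_oracle(dist: np.ndarray):
    """Greedy agglomeration re-scanning the full matrix at every step.

    Returns the merge list [(members_a, members_b, height)] with ties
    broken by the smallest pair of cluster indices.
    """
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    merges = []
    while len(clusters) > 1:
        best = None
        keys = sorted(clusters)
        for ai, a in enumerate(keys):
            for b in keys[ai + 1:]:
                d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0] - 1e-15:
                    best = (d, a, b)
        d, a, b = best
        merges.append((sorted(clusters[a]), sorted(clusters[b]), d))
        clusters[min(a, b)] = clusters[a] + clusters[b]
        if max(a, b) in clusters:
            del clusters[max(a, b)]
    return merges


# ---------------------------------------------------------------------------
# scale-free fit, recomputed from scratch


def scale_free_fit_oracle(k: np.ndarray, n_bins: int = 10) -> float:
    """Equal-width binning of log10(k) and ordinary least squares by hand."""
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if len(k) < 2 or k.max() == k.min():
        return 0.0
    logk = np.log10(k)
    lo, hi = logk.min(), logk.max()
    width = (hi - lo) / n_bins
    xs, ys = [], []
    for b in range(n_bins):
        left = lo + b * width
        right = hi if b == n_bins - 1 else lo + (b + 1) * width
        if b == n_bins - 1:
            mask = (logk >= left) & (logk <= right)
        else:
            mask = (logk >= left) & (logk < right)
        if mask.sum() == 0:
            continue
        xs.append(math.log10(k[mask].mean()))
        ys.append(math.log10(mask.sum()))
    if len(xs) < 2 or max(xs) == min(xs):
        return 0.0
    xs, ys = np.array(xs), np.array(ys)
    xbar, ybar = xs.mean(), ys.mean()
    slope = ((xs - xbar) * (ys - ybar)).sum() / ((xs - xbar) ** 2).sum()
    intercept = ybar - slope * xbar
    ss_res = ((ys - slope * xs - intercept) ** 2).sum()
    ss_tot = ((ys - ybar) ** 2).sum()
    if ss_tot == 0:
        return 0.0
    return float((1 - ss_res / ss_tot) * np.sign(-slope))
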