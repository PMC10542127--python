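"""Marker-gene identification for annotated cell subsets.

Two complementary scans per cluster:

1. AUROC of each gene's logCPM as a classifier of cluster membership
   within the analyzed lineage (mid-rank tie handling); genes with
   AUROC >= 0.75 are AUROC markers.
2. One-versus-all (OVA) pseudobulk differential expression with an
   empirical-Bayes moderated t-test: per-gene linear model
   log2(CPM + 0.5) ~ in_clust on sample x cluster pseudobulk units, gene
   variances shrunk toward a scaled inverse-chi-square prior whose
   hyperparameters (d0, s0^2) are estimated by matching the first two
   moments of log sample variances.  OVA markers: BH-FDR < 0.05 and
   positive log2 fold change.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import special, stats

from .stats import bh_fdr

__all__ = [
    "auroc_scan",
    "estimate_variance_prior",
    "find_markers",
    "ova_moderated_t",
]


def auroc_scan(logcpm, cell_table: pd.DataFrame, cluster, cluster_col: str = "cluster"):
    """Per-gene AUROC for membership in ``cluster`` vs the rest.

    AUROC = U / (n1 * n0) from the rank-sum statistic with mid-ranks for
    ties; invariant to any strictly monotone transform of expression.
    """
    in_cluster = (cell_table[cluster_col] == cluster).to_numpy()
    n1 = int(in_cluster.sum())
    n0 = len(in_cluster) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("cluster and complement must both be non-empty")
    x = np.asarray(sp.csr_matrix(logcpm).todense())
    ranks = stats.rankdata(x, axis=0)
    u = ranks[in_cluster].sum(axis=0) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def _trigamma_inverse(y: float, tol: float = 1e-8) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_variance_prior(s2, d: float):
    """Estimate the (d0, s0^2) scale-inverse-chi-square variance prior.

    Matches the mean and variance of log sample variances to the
    log-F(d, d0) distribution they follow under the prior.  Returns
    ``d0 = inf`` when the observed dispersion of log variances does not
    exceed its sampling floor (all true variances equal).
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2 > 0
    if positive.sum() < 10:
        raise ValueError("need at least 10 genes with positive variance and df >= 1")
    if d < 1:
        raise ValueError("residual degrees of freedom must be >= 1")
    z = np.log(s2[positive])
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - special.polygamma(1, d / 2.0)
    if e_var <= 0:
        # no excess dispersion: point-mass prior at the common variance
        return np.inf, float(np.exp(z.mean()))
    d0 = 2.0 * _trigamma_inverse(e_var)
    if not np.isfinite(d0):
        return np.inf, float(np.exp(z.mean()))
    s0 = np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0)


def posterior_variance(s2, d, d0, s0_sq):
    """Shrunken variance (d0*s0^2 + d*s2) / (d0 + d); s0^2 when d0 = inf."""
    s2 = np.asarray(s2, dtype=float)
    if np.isinf(d0):
        return np.full_like(s2, s0_sq)
    return (d0 * s0_sq + d * s2) / (d0 + d)


def _log2_cpm(pseudobulk: np.ndarray, offset: float = 0.5) -> np.ndarray:
    totals = pseudobulk.sum(axis=1, keepdims=True).astype(float)
    if np.any(totals <= 0):
        raise ValueError("pseudobulk unit with zero total counts")
    return np.log2(pseudobulk / totals * 1e6 + offset)


def ova_moderated_t(
    pseudobulk: np.ndarray,
    units: pd.DataFrame,
    cluster,
    genes=None,
    prior=None,
    cluster_col: str = "cluster",
) -> pd.DataFrame:
    """One-versus-all moderated t-test for one cluster on pseudobulk units.

    ``pseudobulk`` is units x genes integer counts; ``units`` carries the
    cluster label per unit.  ``prior`` optionally fixes (d0, s0^2); by
    default it is estimated from all genes of this scan.  ``d0 = 0``
    recovers the ordinary two-sample t-test.
    """
    in_clust = (units[cluster_col] == cluster).to_numpy().astype(float)
    n = len(in_clust)
    n1 = int(in_clust.sum())
    if n1 < 2 or n - n1 < 2:
        raise ValueError("need >= 2 pseudobulk units inside and outside the cluster")
    y = _log2_cpm(np.asarray(pseudobulk, dtype=float))
    x = np.column_stack([np.ones(n), in_clust])
    xtx_inv = np.linalg.inv(x.T @ x)
    coef = xtx_inv @ x.T @ y  # (2, n_genes)
    resid = y - x @ coef
    d = n - 2
    s2 = (resid**2).sum(axis=0) / d
    v = xtx_inv[1, 1]
    if prior is None:
        d0, s0_sq = estimate_variance_prior(s2, d)
    else:
        d0, s0_sq = prior
    s2_post = posterior_variance(s2, d, d0, s0_sq)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = coef[1] / np.sqrt(s2_post * v)
    t_mod = np.where(s2_post > 0, t_mod, 0.0)
    df_total = d + d0
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)
    p = np.where(np.abs(t_mod) > 0, p, 1.0)
    out = pd.DataFrame(
        {
            "gene": np.asarray(genes) if genes is not None else np.arange(y.shape[1]),
            "cluster": cluster,
            "log2fc": coef[1],
            "t_mod": t_mod,
            "p": p,
        }
    )
    out["fdr"] = bh_fdr(out["p"])
    return out


def find_markers(
    logcpm,
    cell_table: pd.DataFrame,
    pseudobulk: np.ndarray,
    units: pd.DataFrame,
    genes=None,
    clusters=None,
    auroc_threshold: float = 0.75,
    fdr_threshold: float = 0.05,
    cluster_col: str = "cluster",
) -> pd.DataFrame:
    """Combined marker table (AUROC + OVA moderated t) across clusters."""
    if clusters is None:
        clusters = sorted(cell_table[cluster_col].unique())
    frames = []
    for cl in clusters:
        auc = auroc_scan(logcpm, cell_table, cl, cluster_col=cluster_col)
        ova = ova_moderated_t(pseudobulk, units, cl, genes=genes, cluster_col=cluster_col)
        ova = ova.assign(auroc=auc)
        frames.append(ova)
    out = pd.concat(frames, ignore_index=True)
    out["is_auroc_marker"] = out["auroc"] >= auroc_threshold
    out["is_ova_marker"] = (out["fdr"] < fdr_threshold) & (out["log2fc"] > 0)
    return out
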