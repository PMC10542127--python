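"""Permutation-based receptor-ligand interaction scoring.

For each (ligand, receptor, sender cluster, receiver cluster) tuple the
statistic is the mean of the sender's mean ligand logCPM and the
receiver's mean receptor logCPM.  Tuples are excluded unless ligand and
receptor are each expressed in strictly more than 10% of their cluster's
cells and each cluster has at least 20 cells.  Significance comes from
cluster-label permutations shared across all tuples, with the add-one
empirical estimator p = (1 + #{T_b >= T_obs}) / (1 + B) and a strict
p < 0.001 rule; downstream filtering additionally requires a
differentially expressed ligand or receptor, an abundance-enriched
sender or receiver, and membership in the curated pair list.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["filter_interactions", "interaction_statistic", "permutation_test"]

MIN_FRACTION = 0.10
MIN_CELLS = 20
P_THRESHOLD = 0.001


def _cluster_stats(logcpm, codes, n_clusters):
    """Per-cluster (mean, fraction nonzero) for every gene; vectorized."""
    logcpm = sp.csr_matrix(logcpm)
    n_cells = logcpm.shape[0]
    indicator = sp.csr_matrix(
        (np.ones(n_cells), (codes, np.arange(n_cells))), shape=(n_clusters, n_cells)
    )
    sizes = np.bincount(codes, minlength=n_clusters).astype(float)
    sums = np.asarray((indicator @ logcpm).todense())
    nnz = np.asarray((indicator @ (logcpm > 0)).todense())
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / sizes[:, None]
        fracs = nnz / sizes[:, None]
    return means, fracs, sizes


def interaction_statistic(
    logcpm,
    cell_table: pd.DataFrame,
    genes,
    ligand,
    receptor,
    sender,
    receiver,
    cluster_col: str = "cluster",
):
    """Observed statistic for one tuple, or None when a filter excludes it.

    Returns ``(statistic or None, passes_expression_filter)``.
    """
    gene_idx = pd.Index(genes)
    for g in (ligand, receptor):
        if g not in gene_idx:
            raise KeyError(f"unknown gene {g!r}")
    li, ri = gene_idx.get_loc(ligand), gene_idx.get_loc(receptor)
    clusters = pd.Index(sorted(cell_table[cluster_col].unique()))
    codes = clusters.get_indexer(cell_table[cluster_col])
    means, fracs, sizes = _cluster_stats(logcpm, codes, len(clusters))
    si, vi = clusters.get_loc(sender), clusters.get_loc(receiver)
    ok = (
        fracs[si, li] > MIN_FRACTION
        and fracs[vi, ri] > MIN_FRACTION
        and sizes[si] >= MIN_CELLS
        and sizes[vi] >= MIN_CELLS
    )
    if not ok:
        return None, False
    return float((means[si, li] + means[vi, ri]) / 2.0), True


def permutation_test(
    logcpm,
    cell_table: pd.DataFrame,
    pairs: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
    cluster_col: str = "cluster",
) -> pd.DataFrame:
    """Score every tuple in ``pairs`` with shared label permutations.

    ``pairs`` needs columns ligand, receptor, sender, receiver; gene
    names come from ``cell_table.attrs['genes']`` or a ``genes`` column
    index attached by the caller via ``pairs.attrs``.  The same B
    permutations of the cluster labels are reused for all tuples, making
    the full table reproducible for a fixed seed.
    """
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    genes = cell_table.attrs.get("genes")
    if genes is None:
        raise ValueError("cell_table.attrs['genes'] must hold the gene index")
    gene_idx = pd.Index(genes)
    for g in pd.concat([pairs["ligand"], pairs["receptor"]]).unique():
        if g not in gene_idx:
            raise KeyError(f"unknown gene {g!r}")

    clusters = pd.Index(sorted(cell_table[cluster_col].unique()))
    codes = clusters.get_indexer(cell_table[cluster_col])
    need = pd.Index(pd.concat([pairs["ligand"], pairs["receptor"]]).unique())
    sub = sp.csr_matrix(logcpm)[:, gene_idx.get_indexer(need)]

    means, fracs, sizes = _cluster_stats(sub, codes, len(clusters))
    li = need.get_indexer(pairs["ligand"])
    ri = need.get_indexer(pairs["receptor"])
    si = clusters.get_indexer(pairs["sender"])
    vi = clusters.get_indexer(pairs["receiver"])
    t_obs = (means[si, li] + means[vi, ri]) / 2.0
    passes = (
        (fracs[si, li] > MIN_FRACTION)
        & (fracs[vi, ri] > MIN_FRACTION)
        & (sizes[si] >= MIN_CELLS)
        & (sizes[vi] >= MIN_CELLS)
    )

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(pairs))
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        pm, _, _ = _cluster_stats(sub, perm, len(clusters))
        t_b = (pm[si, li] + pm[vi, ri]) / 2.0
        exceed += t_b >= t_obs - 1e-12
    emp_p = (1.0 + exceed) / (1.0 + n_perm)

    out = pairs[["ligand", "receptor", "sender", "receiver"]].copy()
    out["statistic"] = np.where(passes, t_obs, np.nan)
    out["empirical_p"] = np.where(passes, emp_p, np.nan)
    out["passes_expression_filter"] = passes
    out["passes_significance"] = passes & (emp_p < P_THRESHOLD)
    return out


def filter_interactions(
    results: pd.DataFrame,
    de_tables: dict,
    enriched_clusters,
    curated_pairs: pd.DataFrame,
    de_fdr: float = 0.1,
) -> pd.DataFrame:
    """Apply the DE, abundance-enrichment and curated-list filters.

    ``de_tables`` maps cluster -> DE result table (gene, fdr columns);
    ``enriched_clusters`` is the set of abundance-enriched clusters;
    ``curated_pairs`` has ligand/receptor columns.
    """
    if curated_pairs is None or curated_pairs.empty:
        raise ValueError("a non-empty curated receptor-ligand pair list is required")
    curated = set(zip(curated_pairs["ligand"], curated_pairs["receptor"]))
    enriched = set(enriched_clusters)

    def _is_de(cluster, gene):
        table = de_tables.get(cluster)
        if table is None or table.empty:
            return False
        hit = table.loc[table["gene"] == gene, "fdr"]
        return bool((hit < de_fdr).any())

    out = results.copy()
    out["passes_de_filter"] = [
        _is_de(row.sender, row.ligand) or _is_de(row.receiver, row.receptor)
        for row in out.itertuples()
    ]
    out["passes_abundance_filter"] = [
        (row.sender in enriched) or (row.receiver in enriched) for row in out.itertuples()
    ]
    out["in_curated_list"] = [
        (row.ligand, row.receptor) in curated for row in out.itertuples()
    ]
    out["final_call"] = (
        out["passes_expression_filter"]
        & out["passes_significance"]
        & out["passes_de_filter"]
        & out["passes_abundance_filter"]
        & out["in_curated_list"]
    )
    return out
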