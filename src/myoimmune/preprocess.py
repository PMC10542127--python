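"""Cell QC, logCPM normalization, expression summaries and pseudobulk.

Conventions: droplets are kept when the mitochondrial UMI fraction is
strictly below 20% and the number of unique genes detected is strictly
above the compartment threshold (300 for solid-tissue samples, 400 for
blood).  The mitochondrial fraction is computed from a fixed 13-gene
mitochondrial list regardless of what other MT- features exist in the
annotation.  Normalized expression is logCPM = log1p(counts per 100,000)
in natural log.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "MITO_GENES",
    "QCThresholds",
    "expression_summary",
    "log_normalize",
    "mito_fraction",
    "pseudobulk_sum",
    "qc_filter",
]

#: The 13 protein-coding mitochondrial genes used for the mito-UMI fraction.
MITO_GENES = (
    "MT-ND6",
    "MT-CO2",
    "MT-CYB",
    "MT-ND2",
    "MT-ND5",
    "MT-CO1",
    "MT-ND3",
    "MT-ND4",
    "MT-ND1",
    "MT-ATP6",
    "MT-CO3",
    "MT-ND4L",
    "MT-ATP8",
)

#: Compartments treated as solid tissue for the unique-gene threshold.
_TISSUE_COMPARTMENTS = {"heart", "tumor", "control_tissue"}


@dataclass
class QCThresholds:
    """Droplet quality-control thresholds.

    max_mito_fraction : strict upper bound on mitochondrial UMI fraction.
    min_genes_heart / min_genes_blood : strict lower bounds on unique
    genes detected, for solid tissue and PBMC samples respectively.
    """

    max_mito_fraction: float = 0.20
    min_genes_heart: int = 300
    min_genes_blood: int = 400
    mito_gene_list: tuple = field(default=MITO_GENES)

    def __post_init__(self):
        if self.max_mito_fraction <= 0 or self.min_genes_heart <= 0 or self.min_genes_blood <= 0:
            raise ValueError("QC thresholds must be positive")
        if len(self.mito_gene_list) == 0:
            raise ValueError("mitochondrial gene list must be non-empty")


def mito_fraction(counts, genes) -> np.ndarray:
    """Per-cell fraction of UMIs from the fixed mitochondrial gene list."""
    counts = sp.csr_matrix(counts)
    mito_idx = [i for i, g in enumerate(genes) if g in set(MITO_GENES)]
    totals = np.asarray(counts.sum(axis=1)).ravel()
    if not mito_idx:
        return np.zeros(counts.shape[0])
    mito = np.asarray(counts[:, mito_idx].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)
    return frac


def n_genes_detected(counts) -> np.ndarray:
    counts = sp.csr_matrix(counts)
    return np.asarray((counts > 0).sum(axis=1)).ravel()


def qc_filter(cell_table: pd.DataFrame, counts, thresholds: QCThresholds | None = None):
    """Filter low-quality droplets.

    ``cell_table`` must carry a ``compartment`` column; ``mito_frac`` and
    ``n_genes`` columns are used when present (allowing injected QC
    covariates), otherwise both are computed from ``counts``.

    Returns ``(kept cell table, kept counts, report)`` where the report is
    a per-sample DataFrame of kept / dropped tallies.
    """
    thresholds = thresholds or QCThresholds()
    if "compartment" not in cell_table.columns:
        raise ValueError("cell table lacks a 'compartment' column")
    unknown = set(cell_table["compartment"]) - _TISSUE_COMPARTMENTS - {"blood"}
    if unknown:
        raise ValueError(f"unknown compartment(s): {sorted(unknown)}")

    counts = sp.csr_matrix(counts)
    mito = (
        cell_table["mito_frac"].to_numpy(dtype=float)
        if "mito_frac" in cell_table.columns
        else mito_fraction(counts, getattr(cell_table, "genes", []))
    )
    ngene = (
        cell_table["n_genes"].to_numpy()
        if "n_genes" in cell_table.columns
        else n_genes_detected(counts)
    )
    is_blood = (cell_table["compartment"] == "blood").to_numpy()
    min_genes = np.where(is_blood, thresholds.min_genes_blood, thresholds.min_genes_heart)
    keep = (mito < thresholds.max_mito_fraction) & (ngene > min_genes)

    group_col = "sample" if "sample" in cell_table.columns else "compartment"
    report = (
        pd.DataFrame({group_col: cell_table[group_col].to_numpy(), "kept": keep})
        .groupby(group_col)["kept"]
        .agg(n_total="size", n_kept="sum")
        .assign(n_dropped=lambda d: d["n_total"] - d["n_kept"])
        .reset_index()
    )
    return cell_table.loc[keep].copy(), counts[np.flatnonzero(keep)], report


def log_normalize(counts, scale: float = 1e5):
    """logCPM: ln(1 + scale * count / cell_total), sparsity preserved."""
    counts = sp.csr_matrix(counts, dtype=float)
    totals = np.asarray(counts.sum(axis=1)).ravel()
    if np.any(totals <= 0):
        bad = np.flatnonzero(totals <= 0)
        raise ValueError(f"cells with zero total counts at rows {bad[:5].tolist()}")
    norm = counts.multiply(scale / totals[:, None]).tocsr()
    norm.data = np.log1p(norm.data)
    return norm


def pseudobulk_sum(counts, cell_table: pd.DataFrame, sample_col="sample", cluster_col="cluster"):
    """Sum UMI counts per (sample, cluster) unit.

    Returns ``(matrix, units)``: an integer genes-in-columns DataFrame-free
    representation — ``matrix`` is a units x genes ndarray and ``units`` a
    DataFrame with ``sample``, ``cluster`` and ``n_cells``.  Units with
    zero cells never appear.
    """
    if cell_table[cluster_col].isna().any():
        raise ValueError("every cell needs a cluster label")
    counts = sp.csr_matrix(counts)
    codes_s, uniq_s = pd.factorize(cell_table[sample_col], sort=True)
    codes_c, uniq_c = pd.factorize(cell_table[cluster_col], sort=True)
    combo = codes_s.astype(np.int64) * len(uniq_c) + codes_c
    codes, uniq_combo = pd.factorize(combo, sort=True)
    n_units = len(uniq_combo)
    indicator = sp.csr_matrix(
        (np.ones(len(codes)), (codes, np.arange(len(codes)))), shape=(n_units, counts.shape[0])
    )
    mat = np.asarray((indicator @ counts).todense()).astype(np.int64)
    units = pd.DataFrame(
        {
            "sample": uniq_s[uniq_combo // len(uniq_c)],
            "cluster": uniq_c[uniq_combo % len(uniq_c)],
            "n_cells": np.bincount(codes, minlength=n_units),
        }
    )
    return mat, units


def expression_summary(logcpm, cell_table: pd.DataFrame, cluster, cluster_col="cluster"):
    """Per-gene (fraction of nonzero cells, mean logCPM) within one cluster.

    The mean includes zeros; the fraction counts strictly positive values.
    """
    mask = (cell_table[cluster_col] == cluster).to_numpy()
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"cluster {cluster!r} is empty")
    sub = sp.csr_matrix(logcpm)[np.flatnonzero(mask)]
    frac = np.asarray((sub > 0).sum(axis=0)).ravel() / n
    mean = np.asarray(sub.sum(axis=0)).ravel() / n
    return frac, mean
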