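"""Readers and writers for the external formats the pipeline touches.

Supported formats: MatrixMarket coordinate UMI matrices with matching
features/barcodes TSVs (CellRanger-style triplet layout), bulk TCR-beta
clone tables in either AIRR rearrangement dialect or an immunoSEQ-like
dialect, 10x-style single-cell V(D)J contig CSVs, and TSV result tables
with display-rounded companion columns.

Clone identity
--------------
Bulk and single-cell data are matched on a synthetic clone key,
``v_gene|CDR3``.  By default the CDR3 nucleotide junction is used
(``key = v_call stripped to gene level + "|" + junction``); when the
nucleotide junction is unavailable the amino-acid junction is the
fallback.  The key choice is exposed as ``key_on`` so cross-platform
matching can be relaxed to amino-acid level explicitly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "FormatError",
    "clone_key",
    "read_clone_table",
    "read_count_matrix",
    "read_sc_contigs",
    "read_specimen_manifest",
    "write_count_matrix",
    "write_result_table",
]


class FormatError(ValueError):
    """An input file violates its format contract."""


# ---------------------------------------------------------------------------
# count matrices


def read_count_matrix(matrix_path, features_path, barcodes_path):
    """Read a CellRanger-style triplet (MTX + features TSV + barcodes TSV).

    Returns ``(counts, genes, barcodes)`` with ``counts`` a cells x genes
    CSR integer matrix (the on-disk orientation is genes x cells), and the
    gene / barcode identifiers as pandas Index objects.
    """
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # pragma: no cover - scipy error text varies
        raise FormatError(f"cannot parse MatrixMarket file {matrix_path}: {exc}") from exc
    mat = sp.coo_matrix(mat)
    if not np.allclose(mat.data, np.round(mat.data)):
        raise FormatError(f"non-integer values in {matrix_path}")
    genes = pd.read_csv(features_path, sep="\t", header=None).iloc[:, 0]
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None).iloc[:, 0]
    if len(genes) != mat.shape[0]:
        raise FormatError(
            f"{features_path}: {len(genes)} features but matrix has {mat.shape[0]} rows"
        )
    if len(barcodes) != mat.shape[1]:
        raise FormatError(
            f"{barcodes_path}: {len(barcodes)} barcodes but matrix has {mat.shape[1]} columns"
        )
    counts = sp.csr_matrix(mat.T.astype(np.int64))
    counts.eliminate_zeros()
    return counts, pd.Index(genes, name="gene"), pd.Index(barcodes, name="barcode")


def write_count_matrix(counts, genes, barcodes, matrix_path, features_path, barcodes_path):
    """Write a cells x genes sparse matrix as a genes x cells MTX triplet."""
    counts = sp.coo_matrix(counts)
    if counts.shape != (len(barcodes), len(genes)):
        raise ValueError("matrix shape does not match gene/barcode lengths")
    scipy.io.mmwrite(str(matrix_path), counts.T.astype(np.int64), field="integer")
    pd.Series(list(genes)).to_csv(features_path, sep="\t", header=False, index=False)
    pd.Series(list(barcodes)).to_csv(barcodes_path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# TCR clone tables

_V_ALLELE_SEP = "*"

_AIRR_REQUIRED = ["junction", "junction_aa", "v_call", "duplicate_count", "productive"]
_IMMUNOSEQ_REQUIRED = ["nucleotide", "aminoAcid", "vGeneName", "count", "sequenceStatus"]


def _strip_allele(v_call: str) -> str:
    return str(v_call).split(_V_ALLELE_SEP)[0]


def clone_key(v_call, junction_nt=None, junction_aa=None, key_on: str = "nt") -> str:
    """Build the ``v_gene|CDR3`` clone key (nucleotide default, aa fallback)."""
    v = _strip_allele(v_call)
    if key_on == "nt" and junction_nt is not None and str(junction_nt) not in ("", "nan"):
        return f"{v}|{junction_nt}"
    if junction_aa is None or str(junction_aa) in ("", "nan"):
        if junction_nt is not None:
            return f"{v}|{junction_nt}"
        raise FormatError("clone requires a nucleotide or amino-acid junction")
    return f"{v}|{junction_aa}"


def _as_bool(values) -> np.ndarray:
    s = values.astype(str).str.strip().str.upper()
    return s.isin(["T", "TRUE", "1", "YES", "IN"]).to_numpy()


def read_clone_table(path, dialect: str = "airr", key_on: str = "nt") -> pd.DataFrame:
    """Read a bulk TCR-beta clone table and collapse it to unique clones.

    Unproductive rows are dropped; duplicate keys have their counts summed;
    ``frequency`` is count over the total productive count.

    Returns a DataFrame with columns ``clone_key, count, frequency``.
    """
    df = pd.read_csv(path, sep="\t")
    if dialect == "airr":
        required = _AIRR_REQUIRED
    elif dialect == "immunoseq_like":
        required = _IMMUNOSEQ_REQUIRED
    else:
        raise ValueError(f"unknown clone-table dialect {dialect!r}")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    if dialect == "airr":
        productive = _as_bool(df["productive"])
        df = df.loc[productive]
        keys = [
            clone_key(v, nt, aa, key_on=key_on)
            for v, nt, aa in zip(df["v_call"], df["junction"], df["junction_aa"])
        ]
        counts = df["duplicate_count"].astype(int)
    else:
        productive = _as_bool(df["sequenceStatus"])
        df = df.loc[productive]
        keys = [
            clone_key(v, nt, aa, key_on=key_on)
            for v, nt, aa in zip(df["vGeneName"], df["nucleotide"], df["aminoAcid"])
        ]
        counts = df["count"].astype(int)

    out = (
        pd.DataFrame({"clone_key": keys, "count": counts.to_numpy()})
        .groupby("clone_key", sort=True, as_index=False)["count"]
        .sum()
    )
    total = out["count"].sum()
    out["frequency"] = out["count"] / total if total > 0 else 0.0
    return out


def read_sc_contigs(path, key_on: str = "nt"):
    """Map cell barcodes to beta-chain clone keys from a V(D)J contig CSV.

    Only productive TRB contigs are used.  Cells with more than one
    distinct productive beta clone key are treated as ambiguous and
    excluded.  Returns ``(mapping, n_ambiguous)`` where ``mapping`` is a
    pandas Series barcode -> clone key.
    """
    df = pd.read_csv(path)
    required = ["barcode", "chain", "productive", "cdr3_nt", "cdr3", "v_gene"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    keep = (df["chain"].astype(str) == "TRB") & _as_bool(df["productive"])
    df = df.loc[keep]
    if df.empty:
        return pd.Series(dtype=object, name="clone_key"), 0
    df = df.assign(
        clone_key=[
            clone_key(v, nt, aa, key_on=key_on)
            for v, nt, aa in zip(df["v_gene"], df["cdr3_nt"], df["cdr3"])
        ]
    )
    per_cell = df.groupby("barcode")["clone_key"].agg(["nunique", "first"])
    ambiguous = per_cell["nunique"] > 1
    mapping = per_cell.loc[~ambiguous, "first"]
    mapping.name = "clone_key"
    return mapping, int(ambiguous.sum())


# ---------------------------------------------------------------------------
# result tables

_RATIO_COLS = {"or", "odds_ratio", "fold", "fold_ratio", "normalized_ratio"}
_P_COLS = {"p", "fdr", "pvalue", "p_value"}


def _is_p_col(name: str) -> bool:
    low = name.lower()
    return low in _P_COLS or low.endswith("_p") or low.endswith("_fdr")


def format_p(p: float) -> str:
    """Two-significant-figure p-value display (``0.052``, ``8.1e-4``)."""
    if not np.isfinite(p):
        return ""
    if p == 0:
        return "0"
    if p >= 1e-3:
        return f"{float(f'{p:.2g}'):g}"
    mantissa_exp = f"{p:.1e}"  # e.g. 8.1e-04
    mant, exp = mantissa_exp.split("e")
    return f"{mant}e{int(exp)}"


def write_result_table(table: pd.DataFrame, path) -> None:
    """Write a result table as TSV with stable columns plus display copies.

    Odds-ratio / fold columns gain a ``*_display`` rounded to 1 decimal;
    p-value / FDR columns gain a two-significant-figure display.
    """
    out = table.copy()
    for col in table.columns:
        low = col.lower()
        if low in _RATIO_COLS:
            out[f"{col}_display"] = [
                f"{v:.1f}" if np.isfinite(v) else "" for v in table[col].astype(float)
            ]
        elif _is_p_col(col) and pd.api.types.is_numeric_dtype(table[col]):
            out[f"{col}_display"] = [format_p(v) for v in table[col].astype(float)]
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# specimen manifest

COMPARTMENTS = ("heart", "blood", "tumor", "control_tissue")


def read_specimen_manifest(path) -> pd.DataFrame:
    """Read a specimen manifest CSV and validate identifiers and paths."""
    df = pd.read_csv(path)
    required = ["sample_id", "donor_id", "compartment", "group"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample_id values")
    bad = set(df["compartment"]) - set(COMPARTMENTS)
    if bad:
        raise FormatError(f"{path}: unknown compartment(s) {sorted(bad)}")
    base = Path(path).parent
    for col in df.columns:
        if col.endswith("_path"):
            for p in df[col].dropna():
                if not (base / p).exists() and not Path(p).exists():
                    raise FormatError(f"{path}: referenced path {p} does not exist")
    return df


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
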