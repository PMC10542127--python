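"""TCR-beta repertoire analytics.

Clonal expansion calling (> 0.5% of the repertoire and >= 2 reads or
cells), bystander-controlled enrichment testing of expanded clones
against adjacent normal ("control") tissue with Fisher's exact test and
BH-FDR < 5%, Hill diversity profiles over orders 0-4 (with optional
seeded rarefaction), and heart/tumor enriched-set overlap summaries.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .stats import bh_fdr

__all__ = [
    "call_expanded",
    "fisher_exact_2x2",
    "heart_tumor_overlap",
    "hill_diversity",
    "tissue_enrichment",
]

EXPANSION_FREQ = 0.005
EXPANSION_COUNT = 2


def call_expanded(clone_table: pd.DataFrame, mode: str = "bulk") -> pd.DataFrame:
    """Flag expanded clones: frequency strictly > 0.5% AND count >= 2.

    ``mode`` only documents the count unit (reads for bulk, cells for
    single-cell); the rule is identical.
    """
    if mode not in ("bulk", "sc"):
        raise ValueError(f"unknown mode {mode!r}")
    if clone_table.empty or clone_table["count"].sum() == 0:
        raise ValueError("clone table has no reads")
    out = clone_table.copy()
    total = out["count"].sum()
    out["frequency"] = out["count"] / total
    out["expanded"] = (out["frequency"] > EXPANSION_FREQ) & (out["count"] >= EXPANSION_COUNT)
    return out


def fisher_exact_2x2(table):
    """Fisher's exact test on a 2x2 table.

    Returns ``(p_two_sided, p_greater)`` — the two-sided p under the
    minimum-likelihood convention and the one-sided upper-tail p.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("need a 2x2 table of non-negative integers")
    t = np.round(t).astype(np.int64)
    p_two = stats.fisher_exact(t, alternative="two-sided")[1]
    p_greater = stats.fisher_exact(t, alternative="greater")[1]
    return float(p_two), float(p_greater)


def tissue_enrichment(
    tissue_clones: pd.DataFrame,
    control_clones: pd.DataFrame,
    tissue: str = "heart",
    fdr_threshold: float = 0.05,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Test expanded tissue clones for enrichment over control tissue.

    Candidates are the clones called expanded in the tissue of interest.
    Each candidate's 2x2 compares its read counts in tissue vs control
    against the remaining reads (frequencies, not absolute counts, drive
    the comparison).  The one-sided (greater-in-tissue) Fisher p is the
    default; BH correction runs over the candidate set.  The normalized
    ratio divides the tissue frequency by the control frequency, using a
    0.5 / control_total pseudo-frequency when the clone is absent from
    control — the test itself always uses the true zero.
    """
    if tissue_clones["count"].sum() == 0 or control_clones["count"].sum() == 0:
        raise ValueError("both repertoires need positive totals")
    called = call_expanded(tissue_clones)
    candidates = called.loc[called["expanded"]]
    total_t = int(tissue_clones["count"].sum())
    total_c = int(control_clones["count"].sum())
    control = control_clones.set_index("clone_key")["count"]
    if candidates.empty:
        warnings.warn("no expanded clones; empty enrichment result")

    rows = []
    for _, row in candidates.iterrows():
        ct = int(row["count"])
        cc = int(control.get(row["clone_key"], 0))
        table = [[ct, total_t - ct], [cc, total_c - cc]]
        p_two, p_gr = fisher_exact_2x2(table)
        p = p_gr if alternative == "greater" else p_two
        freq_t = ct / total_t
        freq_c = cc / total_c
        denom = freq_c if cc > 0 else 0.5 / total_c
        rows.append(
            {
                "clone_key": row["clone_key"],
                "tissue": tissue,
                "count_tissue": ct,
                "count_control": cc,
                "freq_tissue": freq_t,
                "freq_control": freq_c,
                "normalized_ratio": freq_t / denom,
                "fisher_p": p,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "clone_key", "tissue", "count_tissue", "count_control",
            "freq_tissue", "freq_control", "normalized_ratio", "fisher_p",
        ],
    )
    if not out.empty:
        out["fdr"] = bh_fdr(out["fisher_p"])
        out["enriched"] = out["fdr"] < fdr_threshold
    else:
        out["fdr"] = pd.Series(dtype=float)
        out["enriched"] = pd.Series(dtype=bool)
    return out


def _hill_from_p(p: np.ndarray, q: float) -> float:
    p = p[p > 0]
    if abs(q - 1.0) < 1e-12:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def hill_diversity(
    clone_table: pd.DataFrame,
    q_grid=None,
    rarefy_depth: int | None = None,
    n_boot: int = 200,
    seed: int | None = None,
    min_sequences: int = 100,
) -> pd.DataFrame:
    """Hill diversity profile qD over a grid of orders (default 0-4).

    qD = (sum p_i^q)^(1/(1-q)) with the exp-Shannon limit at q = 1.
    Samples with fewer than ``min_sequences`` total sequences are
    refused.  With ``rarefy_depth`` set, qD is the mean over ``n_boot``
    seeded multinomial resamples at that depth.
    """
    if q_grid is None:
        q_grid = np.linspace(0, 4, 41)
    q_grid = np.asarray(q_grid, dtype=float)
    counts = clone_table["count"].to_numpy()
    n_seq = int(counts.sum())
    if n_seq < min_sequences:
        raise ValueError(
            f"diversity requires >= {min_sequences} total sequences, got {n_seq}"
        )
    if rarefy_depth is None:
        p = counts / n_seq
        qd = np.array([_hill_from_p(p, q) for q in q_grid])
    else:
        if rarefy_depth > n_seq:
            raise ValueError("rarefaction depth exceeds the number of sequences")
        rng = np.random.default_rng(seed)
        p = counts / n_seq
        acc = np.zeros(len(q_grid))
        for _ in range(n_boot):
            sub = rng.multinomial(rarefy_depth, p)
            ps = sub[sub > 0] / rarefy_depth
            acc += np.array([_hill_from_p(ps, q) for q in q_grid])
        qd = acc / n_boot
    return pd.DataFrame({"q": q_grid, "qD": qd, "n_sequences": n_seq})


def heart_tumor_overlap(heart_enriched, tumor_enriched) -> dict:
    """Summarize overlap of heart- and tumor-enriched clone sets.

    Accepts enrichment result tables (uses rows with ``enriched``) or
    plain iterables of clone keys.  Percentages are reported exactly and
    rounded to the nearest whole percent for display.
    """

    def _keys(obj):
        if isinstance(obj, pd.DataFrame):
            if "enriched" in obj.columns:
                obj = obj.loc[obj["enriched"]]
            return set(obj["clone_key"])
        return set(obj)

    heart = _keys(heart_enriched)
    tumor = _keys(tumor_enriched)
    shared = heart & tumor
    pct_heart = 100.0 * len(shared) / len(heart) if heart else 0.0
    pct_tumor = 100.0 * len(shared) / len(tumor) if tumor else 0.0
    return {
        "n_heart": len(heart),
        "n_tumor": len(tumor),
        "n_shared": len(shared),
        "pct_of_heart": pct_heart,
        "pct_of_tumor": pct_tumor,
        "pct_of_heart_display": int(round(pct_heart)),
        "pct_of_tumor_display": int(round(pct_tumor)),
        "shared_keys": sorted(shared),
    }
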