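"""Cross-compartment clonotype sharing between heart and blood.

Heart-expanded TCR-beta clones (union of bulk and single-cell expansion
calls per donor) are tracked into that donor's blood cells; each blood
CD8 subset is then tested per donor with a fixed-effect logistic model

    in_subset ~ 1 + myo_clone

against an intercept-only null by likelihood-ratio test, with BH-FDR
across the donor's subsets and an FDR < 5% enrichment rule.  The donor-
level fatal-versus-nonfatal association is a two-sided Fisher exact test
on the resulting 2x2.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .repertoire import fisher_exact_2x2
from .stats import bh_fdr

__all__ = [
    "fatal_association_test",
    "map_shared_clones_to_heart_subsets",
    "mark_heart_expanded_in_blood",
    "sharing_2x2_logistic",
    "subset_sharing_test",
]


def mark_heart_expanded_in_blood(
    heart_expanded: dict,
    blood_cells: pd.DataFrame,
    donor_col: str = "donor",
    clone_col: str = "clone_key",
):
    """Flag blood cells whose clone key is heart-expanded in the same donor.

    ``heart_expanded`` maps donor -> set of expanded clone keys (the
    caller unions bulk and single-cell calls).  Cross-donor matches are
    never flagged; donors absent from ``heart_expanded`` are dropped with
    a warning.

    Returns ``(flagged blood cell table with a myo_clone column, skipped
    donors)``.
    """
    donors = blood_cells[donor_col].unique()
    skipped = [d for d in donors if d not in heart_expanded]
    if skipped:
        warnings.warn(f"donors without heart TCR data skipped: {skipped}")
    out = blood_cells.loc[~blood_cells[donor_col].isin(skipped)].copy()
    flags = np.zeros(len(out), dtype=bool)
    keys = out[clone_col]
    for donor, expanded in heart_expanded.items():
        m = (out[donor_col] == donor).to_numpy()
        flags[m] = keys[m].isin(set(expanded)).to_numpy()
    out["myo_clone"] = flags
    return out, skipped


def _binom_ll(y: int, n: int) -> float:
    """Binomial log-likelihood at the MLE p = y/n (constant term dropped)."""
    ll = 0.0
    if 0 < y:
        ll += y * np.log(y / n)
    if y < n:
        ll += (n - y) * np.log((n - y) / n)
    return ll


def sharing_2x2_logistic(a: int, b: int, c: int, d: int):
    """Logistic fit of in_subset ~ myo_clone from its sufficient 2x2.

    Cells: a = flagged & in-subset, b = flagged & out, c = unflagged &
    in, d = unflagged & out.  The single-binary-covariate logistic MLE is
    the 2x2 log odds ratio; the LRT against the intercept-only model has
    the closed form 2 * (saturated-by-group loglik - pooled loglik).

    Returns ``(beta1, lrt_stat, p, unstable)`` with ``beta1`` +/- inf and
    ``unstable`` True under separation (a zero cell).
    """
    n1, n0 = a + b, c + d
    if n1 == 0 or n0 == 0:
        return np.nan, 0.0, 1.0, True
    unstable = min(a, b, c, d) == 0
    with np.errstate(divide="ignore"):
        beta1 = np.log(a * d) - np.log(b * c) if not unstable else (
            np.inf if (b == 0 or c == 0) and a + d > 0 else -np.inf
        )
    ll_full = _binom_ll(a, n1) + _binom_ll(c, n0)
    ll_null = _binom_ll(a + c, n1 + n0)
    stat = max(2.0 * (ll_full - ll_null), 0.0)
    p = float(stats.chi2.sf(stat, df=1))
    return float(beta1), stat, p, unstable


def subset_sharing_test(
    blood_cells: pd.DataFrame,
    donor,
    subset_col: str = "cluster",
    donor_col: str = "donor",
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-subset sharing enrichment for one donor's blood cells.

    Requires a boolean ``myo_clone`` column.  Each subset gets a plain
    logistic LRT; BH-FDR runs across the donor's tested subsets.
    """
    cells = blood_cells.loc[blood_cells[donor_col] == donor]
    if cells.empty:
        raise ValueError(f"no blood cells for donor {donor!r}")
    flagged = cells["myo_clone"].to_numpy().astype(bool)
    n_flagged = int(flagged.sum())
    shared_clones = cells.loc[flagged, "clone_key"].nunique() if "clone_key" in cells else np.nan
    rows = []
    for subset in sorted(cells[subset_col].unique()):
        in_subset = (cells[subset_col] == subset).to_numpy()
        a = int((flagged & in_subset).sum())
        b = int((flagged & ~in_subset).sum())
        c = int((~flagged & in_subset).sum())
        d = int((~flagged & ~in_subset).sum())
        if n_flagged == 0:
            beta1, stat, p, unstable = np.nan, np.nan, np.nan, True
            reason = "no heart-expanded clones in this donor's blood"
        else:
            beta1, stat, p, unstable = sharing_2x2_logistic(a, b, c, d)
            reason = ""
        rows.append(
            {
                "donor": donor,
                "blood_subset": subset,
                "n_cells_subset": a + c,
                "n_shared_cells_subset": a,
                "beta1": beta1,
                "or": float(np.exp(beta1)) if np.isfinite(beta1) else (
                    np.inf if beta1 == np.inf else (0.0 if beta1 == -np.inf else np.nan)
                ),
                "lrt_stat": stat,
                "lrt_p": p,
                "unstable": unstable,
                "reason": reason,
                "n_unique_shared_clones": shared_clones,
                "n_total_shared_cells": n_flagged,
            }
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["lrt_p"])
    out["significant"] = out["fdr"] < fdr_threshold
    return out


def fatal_association_test(sharing_significant: pd.Series, fatal: pd.Series):
    """Two-sided Fisher test: significant sharing vs fatal outcome.

    Both inputs are boolean Series indexed by donor.  Returns
    ``(table, p)`` with the 2x2 as [[fatal & sharing, fatal & not],
    [non-fatal & sharing, non-fatal & not]].
    """
    idx = sharing_significant.index.intersection(fatal.index)
    s = sharing_significant.loc[idx].astype(bool)
    f = fatal.loc[idx].astype(bool)
    table = np.array(
        [
            [int((f & s).sum()), int((f & ~s).sum())],
            [int((~f & s).sum()), int((~f & ~s).sum())],
        ]
    )
    if table.sum(axis=1).min() == 0:
        warnings.warn("one outcome class is empty; Fisher p = 1")
        return table, 1.0
    p_two, _ = fisher_exact_2x2(table)
    return table, p_two


def map_shared_clones_to_heart_subsets(
    heart_cells: pd.DataFrame,
    shared_keys,
    subset_col: str = "cluster",
    clone_col: str = "clone_key",
    min_cells: int = 10,
):
    """Count heart cells per subset carrying a blood-shared clone key.

    Returns ``(per-subset counts DataFrame, low_evidence)``; donors with
    ``min_cells`` or fewer qualifying cells are flagged low-evidence.
    """
    shared_keys = set(shared_keys)
    carrying = heart_cells.loc[heart_cells[clone_col].isin(shared_keys)]
    counts = (
        carrying.groupby(subset_col).size().reindex(
            sorted(heart_cells[subset_col].unique()), fill_value=0
        )
    ).rename("n_shared_cells").reset_index()
    low_evidence = len(carrying) <= min_cells
    return counts, low_evidence
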