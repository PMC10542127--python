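"""Serum analyte comparisons and immunohistochemistry density ratios.

Serum analytes are compared case vs control on ln(x + 1) values with a
Welch two-sided t-test per analyte; the flagging rule is raw p < 0.05
with no multiplicity adjustment (recorded in the output).  Density
comparisons report the fold ratio of region means (cells per 1e5 total
cells) with a one-sided two-sample t-test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["density_fold_compare", "serum_compare"]


def serum_compare(
    serum_table: pd.DataFrame,
    groups: pd.Series,
    case_label: str = "case",
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-analyte two-sided t-test on ln(x + 1) transformed values.

    Parameters
    ----------
    serum_table : long DataFrame with columns analyte, donor, value.
    groups : Series donor -> group label.
    equal_var : use Student's pooled-variance t instead of Welch.
    """
    if (serum_table["value"] < 0).any():
        raise ValueError("negative serum analyte value")
    merged = serum_table.assign(group=groups.loc[serum_table["donor"]].to_numpy())
    rows = []
    for analyte, sub in merged.groupby("analyte", sort=True):
        x = np.log1p(sub.loc[sub["group"] == case_label, "value"].to_numpy())
        y = np.log1p(sub.loc[sub["group"] != case_label, "value"].to_numpy())
        if len(x) < 2 or len(y) < 2:
            raise ValueError(f"analyte {analyte!r} needs >= 2 donors per group")
        t, p = stats.ttest_ind(x, y, equal_var=equal_var)
        if not np.isfinite(p):  # both groups constant
            t, p = 0.0, 1.0
        rows.append(
            {
                "analyte": analyte,
                "n_case": len(x),
                "n_control": len(y),
                "mean_log_case": x.mean(),
                "mean_log_control": y.mean(),
                "t_stat": t,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["flagged"] = out["p"] < 0.05
    out.attrs["note"] = "raw two-sided t-test p-values; no multiplicity adjustment"
    return out


def density_fold_compare(
    densities: pd.DataFrame,
    region_a: str,
    region_b: str,
) -> dict:
    """Fold ratio of mean densities (region_a / region_b) + one-sided t.

    ``densities`` is a long DataFrame with columns region, sample,
    density (cells per 1e5 total cells).  The test is one-sided for
    region_a greater; with fewer than 2 samples in either region only
    the ratio is reported.
    """
    a = densities.loc[densities["region"] == region_a, "density"].to_numpy(dtype=float)
    b = densities.loc[densities["region"] == region_b, "density"].to_numpy(dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("each region needs at least one sample")
    mean_a, mean_b = a.mean(), b.mean()
    if mean_b == 0:
        return {
            "region_a": region_a, "region_b": region_b,
            "mean_a": mean_a, "mean_b": mean_b,
            "fold_ratio": np.nan, "p": np.nan,
            "reason": "zero denominator mean",
        }
    fold = mean_a / mean_b
    if len(a) >= 2 and len(b) >= 2:
        _, p = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    else:
        p = np.nan
    return {
        "region_a": region_a,
        "region_b": region_b,
        "mean_a": mean_a,
        "mean_b": mean_b,
        "fold_ratio": float(fold),
        "fold_display": f"{fold:.1f}-fold",
        "p": float(p) if np.isfinite(p) else np.nan,
        "reason": "",
    }
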