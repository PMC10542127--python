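"""Shared statistical utilities used across analysis modules."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_fdr"]


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Parameters
    ----------
    pvalues : array-like of float
        Raw p-values in [0, 1].  NaN entries are passed through unchanged
        and do not count toward the number of tests.

    Returns
    -------
    numpy.ndarray
        Adjusted values in the input order, monotone in the usual step-up
        sense and capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    mask = ~np.isnan(p)
    if np.any((p[mask] < 0) | (p[mask] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if mask.sum() > 0:
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out
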