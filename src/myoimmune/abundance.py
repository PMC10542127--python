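"""Differential cell-subset abundance via mixed-effects logistic regression.

Each cell subset is tested with the model

    cluster ~ 1 + outcome + (1|donor)

where ``cluster`` is a per-cell binary membership indicator, ``outcome``
the case/control label, and the donor enters as a Gaussian random
intercept.  Because the only covariate is donor-constant, the cell-level
Bernoulli likelihood collapses exactly to donor-level binomial counts
(y_d successes of n_d cells), which is how the model is fit here.  The
marginal likelihood integrates the random intercept out with adaptive
Gauss-Hermite quadrature; significance of the outcome term comes from a
likelihood-ratio test against the intercept-only (plus random intercept)
null, with Benjamini-Hochberg correction across the tested subsets and
an FDR < 0.10 significance rule.

Severity analysis regresses log(troponin) on log(subset abundance) by
ordinary least squares, using the troponin value measured within +/- 2
days of tissue collection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .stats import bh_fdr

__all__ = [
    "BinomialMixedModel",
    "BinomialMixedResults",
    "diff_abundance",
    "fit_mixed_logistic",
    "severity_regression",
]

_GH_NODES = 25


def _expit(x):
    return special.expit(x)


class BinomialMixedModel:
    """Binomial logistic regression with a per-group Gaussian random intercept.

    Parameters
    ----------
    successes, totals : arrays of length n_groups
        Number of "in subset" cells and total cells per donor.
    exog : array (n_groups,) or (n_groups, k)
        Fixed-effect covariates (an intercept column is added internally).
    n_quad : int
        Number of adaptive Gauss-Hermite nodes.
    """

    def __init__(self, successes, totals, exog, n_quad: int = _GH_NODES):
        self.y = np.asarray(successes, dtype=float)
        self.n = np.asarray(totals, dtype=float)
        x = np.asarray(exog, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        self.x = np.column_stack([np.ones(len(self.y)), x])
        if np.any(self.n < 1):
            raise ValueError("every donor needs at least one cell")
        if len(self.y) != len(self.n) or len(self.y) != self.x.shape[0]:
            raise ValueError("successes, totals and exog must have equal length")
        self.k = self.x.shape[1]
        nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
        self._z = nodes
        self._logw = np.log(weights) + nodes**2  # for exp-weighted adaptive GH
        self._log_binom = (
            special.gammaln(self.n + 1)
            - special.gammaln(self.y + 1)
            - special.gammaln(self.n - self.y + 1)
        )

    # -- likelihood ---------------------------------------------------------

    def _modes(self, eta, sigma2):
        """Conditional mode and curvature of the per-donor integrand."""
        u = np.zeros_like(eta)
        for _ in range(50):
            p = _expit(eta + u)
            g = self.y - self.n * p - u / sigma2
            h = -self.n * p * (1 - p) - 1.0 / sigma2
            step = g / h
            u = u - step
            if np.max(np.abs(step)) < 1e-10:
                break
        p = _expit(eta + u)
        h = -self.n * p * (1 - p) - 1.0 / sigma2
        return u, h

    def loglike(self, params) -> float:
        """Marginal log-likelihood at params = (beta..., sigma)."""
        beta = np.asarray(params[: self.k], dtype=float)
        sigma = float(params[self.k])
        eta = self.x @ beta
        if sigma < 1e-8:
            p = _expit(eta)
            ll = self.y * np.log(np.clip(p, 1e-300, 1)) + (self.n - self.y) * np.log(
                np.clip(1 - p, 1e-300, 1)
            )
            return float(np.sum(ll + self._log_binom))
        sigma2 = sigma**2
        u0, h = self._modes(eta, sigma2)
        tau = 1.0 / np.sqrt(-h)
        # u-grid: (n_donors, n_nodes)
        u = u0[:, None] + np.sqrt(2.0) * tau[:, None] * self._z[None, :]
        eta_u = eta[:, None] + u
        ll_bin = self.y[:, None] * eta_u - self.n[:, None] * np.logaddexp(0.0, eta_u)
        ll_pri = -0.5 * u**2 / sigma2 - 0.5 * np.log(2 * np.pi * sigma2)
        log_terms = self._logw[None, :] + ll_bin + ll_pri
        log_int = special.logsumexp(log_terms, axis=1) + np.log(np.sqrt(2.0) * tau)
        return float(np.sum(log_int + self._log_binom))

    # -- fitting ------------------------------------------------------------

    def fit(self, start=None) -> "BinomialMixedResults":
        if start is None:
            p_pool = np.clip((self.y.sum() + 0.5) / (self.n.sum() + 1.0), 1e-6, 1 - 1e-6)
            start = np.r_[special.logit(p_pool), np.zeros(self.k - 1), 0.5]
        start = np.asarray(start, dtype=float)

        def neg(params):
            return -self.loglike(params)

        bounds = [(None, None)] * self.k + [(0.0, 20.0)]
        res = optimize.minimize(neg, start, method="L-BFGS-B", bounds=bounds)
        # boundary sigma: refit the plain logistic likelihood exactly
        params = res.x.copy()
        if params[self.k] < 1e-4:
            res0 = optimize.minimize(
                lambda b: -self.loglike(np.r_[b, 0.0]), params[: self.k], method="BFGS"
            )
            params = np.r_[res0.x, 0.0]
            llf = -res0.fun
        else:
            llf = -res.fun
        if not res.success and not np.isfinite(llf):
            raise RuntimeError(f"mixed-logistic fit did not converge: {res.message}")
        unstable = self._detect_separation()
        cov = self._cov_params(params)
        return BinomialMixedResults(self, params, llf, cov, unstable)

    def _detect_separation(self) -> bool:
        if self.k < 2:
            return False
        for val in np.unique(self.x[:, 1]):
            m = self.x[:, 1] == val
            if np.all(self.y[m] == 0) or np.all(self.y[m] == self.n[m]):
                return True
        return False

    def _cov_params(self, params):
        """Inverse observed information by central finite differences."""
        at_boundary = params[self.k] < 1e-4
        free = list(range(self.k)) if at_boundary else list(range(self.k + 1))
        m = len(free)
        h = 1e-4 * np.maximum(np.abs(params[free]), 1.0)
        hess = np.zeros((m, m))
        f0 = self.loglike(params)
        for a in range(m):
            for b in range(a, m):
                pa, pb = np.zeros_like(params), np.zeros_like(params)
                pa[free[a]] = h[a]
                pb[free[b]] = h[b]
                if a == b:
                    f_pp = self.loglike(params + pa)
                    f_mm = self.loglike(params - pa)
                    hess[a, a] = (f_pp - 2 * f0 + f_mm) / h[a] ** 2
                else:
                    f_pp = self.loglike(params + pa + pb)
                    f_pm = self.loglike(params + pa - pb)
                    f_mp = self.loglike(params - pa + pb)
                    f_mm = self.loglike(params - pa - pb)
                    hess[a, b] = hess[b, a] = (f_pp - f_pm - f_mp + f_mm) / (4 * h[a] * h[b])
        cov = np.full((self.k + 1, self.k + 1), np.nan)
        try:
            cov_free = np.linalg.inv(-hess)
            for i, fi in enumerate(free):
                for j, fj in enumerate(free):
                    cov[fi, fj] = cov_free[i, j]
        except np.linalg.LinAlgError:
            pass
        return cov


@dataclass
class BinomialMixedResults:
    """Fit results: fixed effects, random-intercept SD, covariance, loglik."""

    model: BinomialMixedModel
    params: np.ndarray
    llf: float
    cov_params: np.ndarray
    unstable: bool

    @property
    def beta(self) -> np.ndarray:
        return self.params[: self.model.k]

    @property
    def sigma(self) -> float:
        return float(self.params[self.model.k])

    @property
    def bse(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.sqrt(np.diag(self.cov_params))

    def conf_int_or(self, idx: int = 1, alpha: float = 0.05):
        """Wald confidence interval for exp(beta[idx]) (odds-ratio scale)."""
        z = stats.norm.ppf(1 - alpha / 2)
        b, se = self.beta[idx], self.bse[idx]
        if not np.isfinite(se):
            return (0.0, np.inf)
        return (float(np.exp(b - z * se)), float(np.exp(b + z * se)))

    def lrt(self, null: "BinomialMixedResults"):
        """Likelihood-ratio test against a nested null fit: (stat, p)."""
        stat = 2.0 * (self.llf - null.llf)
        if stat < 0:
            if stat < -1e-6:
                warnings.warn(f"negative LRT statistic {stat:.3g} clamped to 0")
            stat = 0.0
        return stat, float(stats.chi2.sf(stat, df=1))

    def summary(self) -> str:
        lines = ["Binomial mixed logistic (donor random intercept)", "-" * 50]
        names = [f"beta{i}" for i in range(self.model.k)]
        for name, b, se in zip(names, self.beta, self.bse):
            lines.append(f"{name:>8s}  {b: .4f}  (SE {se:.4f})")
        lines.append(f"   sigma  {self.sigma: .4f}")
        lines.append(f"  loglik  {self.llf: .4f}")
        if self.unstable:
            lines.append("  WARNING: separation detected; estimates unstable")
        return "\n".join(lines)


def fit_mixed_logistic(successes, totals, group):
    """Convenience wrapper: fit the full model and return a results object."""
    return BinomialMixedModel(successes, totals, group).fit()


def diff_abundance(
    cell_table: pd.DataFrame,
    sample_meta: pd.DataFrame,
    clusters=None,
    donor_col: str = "donor",
    cluster_col: str = "cluster",
    group_col: str = "group",
    case_label: str = "case",
    fdr_threshold: float = 0.10,
) -> pd.DataFrame:
    """Per-cluster differential-abundance scan (LRT, BH-FDR < 10%).

    Cells are collapsed to per-donor (y_d, n_d) binomial counts per
    cluster; each cluster is tested with the full vs. intercept-only
    mixed logistic model.
    """
    meta = sample_meta.drop_duplicates(donor_col).set_index(donor_col)
    donors = cell_table[donor_col].unique()
    group = (meta.loc[donors, group_col] == case_label).astype(float).to_numpy()
    if (group == 1).sum() < 2 or (group == 0).sum() < 2:
        raise ValueError("need at least 2 donors per group")
    totals = cell_table.groupby(donor_col).size().loc[donors].to_numpy(dtype=float)
    if clusters is None:
        clusters = sorted(cell_table[cluster_col].unique())

    rows = []
    for cl in clusters:
        y = (
            cell_table.loc[cell_table[cluster_col] == cl]
            .groupby(donor_col)
            .size()
            .reindex(donors, fill_value=0)
            .to_numpy(dtype=float)
        )
        if y.sum() == 0:
            warnings.warn(f"cluster {cl!r} absent from all donors; skipped")
            continue
        full = BinomialMixedModel(y, totals, group).fit()
        null = BinomialMixedModel(y, totals, np.zeros((len(y), 0))).fit()
        stat, p = full.lrt(null)
        ci_low, ci_high = full.conf_int_or(1)
        rows.append(
            {
                "cluster": cl,
                "beta1": full.beta[1],
                "or": float(np.exp(full.beta[1])),
                "ci_low": ci_low,
                "ci_high": ci_high,
                "sigma": full.sigma,
                "lrt_stat": stat,
                "p": p,
                "unstable": full.unstable,
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["fdr"] = bh_fdr(out["p"])
        out["significant"] = out["fdr"] < fdr_threshold
    return out


def severity_regression(
    fractions: pd.DataFrame,
    troponin: pd.DataFrame,
    max_offset_days: float = 2.0,
) -> pd.DataFrame:
    """Regress log(troponin) on log(subset fraction), one fit per cluster.

    Parameters
    ----------
    fractions : DataFrame with columns sample, cluster, fraction.
    troponin : DataFrame with columns sample, troponin and optionally
        offset_days (measurement offset from tissue collection; samples
        beyond ``max_offset_days`` in absolute value are excluded).
    """
    trop = troponin.copy()
    if "offset_days" in trop.columns:
        trop = trop.loc[trop["offset_days"].abs() <= max_offset_days]
    trop = trop.loc[trop["troponin"] > 0].set_index("sample")["troponin"]

    rows = []
    for cl, sub in fractions.groupby("cluster"):
        sub = sub.loc[sub["fraction"] > 0]
        merged = sub.set_index("sample").join(trop, how="inner").dropna()
        n = len(merged)
        if n < 3:
            rows.append(
                {"cluster": cl, "slope": np.nan, "slope_se": np.nan, "p": np.nan, "n": n,
                 "reason": "fewer than 3 usable samples"}
            )
            continue
        logy = np.log(merged["troponin"].to_numpy())
        if np.ptp(logy) < 1e-12:  # constant response: slope 0, uninformative
            rows.append(
                {"cluster": cl, "slope": 0.0, "slope_se": 0.0, "p": 1.0, "n": n, "reason": ""}
            )
            continue
        fit = stats.linregress(np.log(merged["fraction"]), logy)
        rows.append(
            {"cluster": cl, "slope": fit.slope, "slope_se": fit.stderr,
             "p": fit.pvalue, "n": n, "reason": ""}
        )
    return pd.DataFrame(rows)
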