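"""Multiple imputation of missing site-period concentrations.

Chained equations with a Bayesian normal linear regression per period
column: each column with missing cells is regressed on all other period
columns plus site-type indicator variables, the regression parameters are
drawn from their posterior (normal-inverse-chi-square under the standard
noninformative prior), and the missing cells are filled with posterior
predictive draws. Sweeping all columns a fixed number of times and
repeating the whole chain m times (default 10) yields m completed tables.

Per-imputation model fits are pooled with Rubin's rules; the total variance
is T = W + (1 + 1/m) B and the reference t distribution uses the
Barnard-Rubin small-sample degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import period_columns


@dataclass
class ImputedCampaign:
    m: int
    tables: list[pd.DataFrame]  # m completed site tables

    def annual_means(self) -> pd.DataFrame:
        """Per-imputation annual mean per site (unweighted over periods)."""
        cols = period_columns(self.tables[0])
        data = {f"imp_{k + 1}": t[cols].mean(axis=1) for k, t in enumerate(self.tables)}
        out = pd.DataFrame(data)
        out.index = self.tables[0]["site_id"].values
        return out

    def consensus_annual_mean(self) -> pd.Series:
        """Across-imputation mean of the per-imputation annual means."""
        return self.annual_means().mean(axis=1)


def _design(filled: np.ndarray, dummies: np.ndarray, j: int) -> np.ndarray:
    other = np.delete(filled, j, axis=1)
    return np.column_stack([np.ones(len(filled)), dummies, other])


def _bayes_draw(X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """Posterior draw of (beta, sigma2) for a normal linear model.

    Uses the pseudoinverse so rank-deficient designs (few observed rows,
    collinear periods) degrade to the minimum-norm fit; with a residual
    variance that is numerically zero the draw collapses to the point
    estimate, which is what a noise-free table should produce.
    """
    n, p = X.shape
    XtX = X.T @ X
    XtX_inv = np.linalg.pinv(XtX)
    beta_hat = XtX_inv @ (X.T @ y)
    resid = y - X @ beta_hat
    dof = max(n - np.linalg.matrix_rank(X), 1)
    s2 = float(resid @ resid) / dof
    if s2 < 1e-12:
        return beta_hat, 0.0
    sigma2 = s2 * dof / rng.chisquare(dof)
    cov = sigma2 * XtX_inv
    cov = (cov + cov.T) / 2.0
    # eigenvalue-clipped sampling; pinv covariances can be semi-definite
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    beta = beta_hat + evecs @ (np.sqrt(evals) * rng.standard_normal(p))
    return beta, sigma2


def impute_missing(
    table: pd.DataFrame, m: int = 10, seed: int = 0, n_sweeps: int = 10
) -> ImputedCampaign:
    """Multiply impute the period columns of a site table.

    Requires every site to have at least one observed period and every
    period column at least one observed value. Observed cells are never
    modified; with no missing cells the m tables are identical copies.
    """
    if m < 2:
        raise ValueError("need m >= 2 imputations")
    cols = period_columns(table)
    if not cols:
        raise ValueError("site table has no period columns")
    Y = table[cols].to_numpy(float)
    miss = np.isnan(Y)
    if miss.all(axis=1).any():
        raise ValueError("a site has no observed period at all")
    if miss.all(axis=0).any():
        raise ValueError("a period column is entirely missing")

    site_type = table["site_type"].astype(str)
    types = sorted(site_type.unique())
    dummies = np.column_stack([(site_type == t).to_numpy(float) for t in types[1:]]) if len(types) > 1 else np.empty((len(table), 0))

    seeds = np.random.SeedSequence(seed).spawn(m)
    tables = []
    for k in range(m):
        rng = np.random.default_rng(seeds[k])
        filled = Y.copy()
        col_means = np.nanmean(Y, axis=0)
        for j in range(len(cols)):
            filled[miss[:, j], j] = col_means[j]
        if miss.any():
            for _ in range(n_sweeps):
                for j in range(len(cols)):
                    mj = miss[:, j]
                    if not mj.any():
                        continue
                    X = _design(filled, dummies, j)
                    beta, sigma2 = _bayes_draw(X[~mj], Y[~mj, j], rng)
                    pred = X[mj] @ beta
                    if sigma2 > 0:
                        pred = pred + rng.normal(0.0, np.sqrt(sigma2), size=mj.sum())
                    filled[mj, j] = pred
        out = table.copy()
        out[cols] = filled
        tables.append(out)
    return ImputedCampaign(m=m, tables=tables)


def annual_means(campaign: ImputedCampaign) -> pd.DataFrame:
    """Per-imputation site-mean table (sites x imputations)."""
    return campaign.annual_means()


def pool_estimates(
    estimates: np.ndarray,
    standard_errors: np.ndarray,
    n_complete_dof: float | None = None,
    names: list[str] | None = None,
) -> pd.DataFrame:
    """Pool m regression fits with Rubin's rules.

    ``estimates`` and ``standard_errors`` are (m, p) arrays. Returns one row
    per parameter with the pooled estimate Q_bar, within-imputation variance
    W (mean squared SE), between-imputation variance B (sample variance of
    the estimates), total variance T = W + (1 + 1/m) B, Barnard-Rubin
    degrees of freedom and a two-sided p-value. ``n_complete_dof`` is the
    complete-data residual dof (n - p - 1); when omitted the large-sample
    (infinite) reference is used.
    """
    Q = np.atleast_2d(np.asarray(estimates, dtype=float))
    U = np.atleast_2d(np.asarray(standard_errors, dtype=float)) ** 2
    m, p = Q.shape
    if m < 2:
        raise ValueError("need m >= 2 fits to pool")
    q_bar = Q.mean(axis=0)
    W = U.mean(axis=0)
    B = Q.var(axis=0, ddof=1)
    T = W + (1.0 + 1.0 / m) * B

    df = np.full(p, np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = (1.0 + 1.0 / m) * B / T
    lam = np.where(T > 0, lam, 0.0)
    for i in range(p):
        if lam[i] <= 0:
            df[i] = n_complete_dof if n_complete_dof is not None else np.inf
            continue
        nu_old = (m - 1) / lam[i] ** 2
        if n_complete_dof is None or not np.isfinite(n_complete_dof):
            df[i] = nu_old
        else:
            nu_com = n_complete_dof
            nu_obs = (nu_com + 1.0) / (nu_com + 3.0) * nu_com * (1.0 - lam[i])
            df[i] = nu_old * nu_obs / (nu_old + nu_obs)

    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(T > 0, q_bar / np.sqrt(T), np.where(q_bar == 0, 0.0, np.inf))
    pval = np.empty(p)
    for i in range(p):
        if np.isinf(t_stat[i]):
            pval[i] = 0.0
        elif np.isfinite(df[i]):
            pval[i] = 2.0 * stats.t.sf(abs(t_stat[i]), df[i])
        else:
            pval[i] = 2.0 * stats.norm.sf(abs(t_stat[i]))

    out = pd.DataFrame(
        {"estimate": q_bar, "W": W, "B": B, "T": T, "se": np.sqrt(T), "df": df, "p_value": pval}
    )
    if names is not None:
        out.index = names
    return out
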