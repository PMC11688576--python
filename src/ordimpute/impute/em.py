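"""Expectation-Maximization imputation under a multivariate normal model.

``em_fit`` runs EM for the mean vector and covariance matrix of a
multivariate normal given an incomplete matrix: the E step computes, per
row, the conditional mean and covariance of the missing block given the
observed block and accumulates expected sufficient statistics; the M step
re-estimates (mu, Sigma) from them.  The observed-data log-likelihood is
tracked each iteration and is guaranteed non-decreasing.

``em_impute`` fills missing cells with the conditional mean given the
observed cells and, by default, adds a residual drawn from the conditional
normal distribution so that imputed values carry the model's variability
rather than collapsing onto regression predictions.

Stopping rule: maximum relative change across all entries of mu and Sigma
below ``tol`` (default 1e-4), or ``max_iter`` iterations (default 1000).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .base import BaseImputer, check_incomplete_matrix

__all__ = ["MvnParams", "em_fit", "em_impute", "EMImputer"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class MvnParams:
    """Fitted multivariate-normal parameters and EM diagnostics."""

    mu: np.ndarray
    sigma: np.ndarray
    loglik_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


def _ridge_solve(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cholesky solve of the SPD system a x = b, with a small ridge added
    when the factorization fails (near-singular observed blocks can occur
    with few ordinal categories)."""
    try:
        c, low = linalg.cho_factor(a, check_finite=False)
    except linalg.LinAlgError:
        ridge = 1e-8 * np.trace(a) / a.shape[0] + 1e-12
        c, low = linalg.cho_factor(
            a + ridge * np.eye(a.shape[0]), check_finite=False
        )
    return linalg.cho_solve((c, low), b, check_finite=False)


def _patterns(missing: np.ndarray):
    """Group row indices by missingness pattern."""
    _, inverse = np.unique(missing, axis=0, return_inverse=True)
    groups: dict[int, list[int]] = {}
    for i, g in enumerate(inverse):
        groups.setdefault(int(g), []).append(i)
    for rows in groups.values():
        yield np.array(rows), missing[rows[0]]


def _loglik(X: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> float:
    """Observed-data log-likelihood: sum of log N(x_o; mu_o, Sigma_oo)."""
    total = 0.0
    missing = np.isnan(X)
    for rows, miss in _patterns(missing):
        o = ~miss
        k = int(o.sum())
        if k == 0:
            continue
        s_oo = sigma[np.ix_(o, o)]
        dev = X[np.ix_(rows, o)] - mu[o]
        sign, logdet = np.linalg.slogdet(s_oo)
        if sign <= 0:  # ridge keeps this from mattering in practice
            s_oo = s_oo + (1e-8 * np.trace(s_oo) / k + 1e-12) * np.eye(k)
            sign, logdet = np.linalg.slogdet(s_oo)
        sol = _ridge_solve(s_oo, dev.T)
        quad = np.einsum("ij,ji->i", dev, sol)
        total += -0.5 * (len(rows) * (k * _LOG2PI + logdet) + quad.sum())
    return float(total)


def em_fit(X, tol: float = 1e-4, max_iter: int = 1000) -> MvnParams:
    """EM estimation of (mu, Sigma) from an incomplete matrix.

    Covariance uses the maximum-likelihood 1/n normalization.  On complete
    data the first iteration is already a fixed point, so the closed-form
    ML estimates are returned with ``n_iter = 1``.
    """
    X = check_incomplete_matrix(X)
    n, p = X.shape
    missing = np.isnan(X)

    # init: column means, ML covariance of the mean-filled matrix
    mu = np.nanmean(X, axis=0)
    filled = np.where(missing, mu, X)
    centered = filled - filled.mean(axis=0)
    sigma = centered.T @ centered / n
    sigma += 1e-6 * np.eye(p) * max(np.trace(sigma) / p, 1.0) * (missing.any())

    trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        trace.append(_loglik(X, mu, sigma))
        ex = np.empty_like(X)
        exx_corr = np.zeros((p, p))  # sum of conditional covariances
        for rows, miss in _patterns(missing):
            o = ~miss
            if not miss.any():
                ex[rows] = X[rows]
                continue
            if not o.any():
                ex[rows] = mu
                exx_corr += len(rows) * sigma
                continue
            s_oo = sigma[np.ix_(o, o)]
            s_mo = sigma[np.ix_(miss, o)]
            dev = X[np.ix_(rows, o)] - mu[o]
            beta = _ridge_solve(s_oo, s_mo.T)  # (n_o, n_m)
            cond_mean = mu[miss] + dev @ beta
            cond_cov = sigma[np.ix_(miss, miss)] - s_mo @ beta
            block = np.zeros((p, p))
            block[np.ix_(miss, miss)] = cond_cov
            exx_corr += len(rows) * block
            ex[rows] = X[rows]
            ex[np.ix_(rows, np.flatnonzero(miss))] = cond_mean
        mu_new = ex.mean(axis=0)
        dev_full = ex - mu_new
        sigma_new = (dev_full.T @ dev_full + exx_corr) / n

        theta_old = np.concatenate([mu, sigma.ravel()])
        theta_new = np.concatenate([mu_new, sigma_new.ravel()])
        rel = np.max(np.abs(theta_new - theta_old) / (np.abs(theta_old) + 1e-8))
        mu, sigma = mu_new, sigma_new
        if rel < tol:
            converged = True
            break
    return MvnParams(
        mu=mu, sigma=sigma, loglik_trace=trace, n_iter=n_iter, converged=converged
    )


def _psd_sqrt(cov: np.ndarray) -> np.ndarray:
    """Symmetric square root with negative eigenvalues clipped to zero."""
    sym = 0.5 * (cov + cov.T)
    w, v = np.linalg.eigh(sym)
    return v * np.sqrt(np.clip(w, 0.0, None))


def em_impute(
    X,
    params: MvnParams,
    stochastic: bool = True,
    seed: int | None = None,
) -> np.ndarray:
    """Conditional-mean imputation under fitted MVN parameters.

    With ``stochastic=True`` (default) a residual drawn from the row's
    conditional covariance is added, so the imputed matrix preserves the
    model's variances and covariances instead of shrinking toward the
    regression surface.
    """
    X = check_incomplete_matrix(X, require_observed_columns=False)
    p = X.shape[1]
    if params.mu.shape != (p,):
        raise ValueError(
            f"params dimension {params.mu.shape[0]} does not match p={p}"
        )
    rng = np.random.default_rng(seed)
    out = X.copy()
    missing = np.isnan(X)
    mu, sigma = params.mu, params.sigma
    for rows, miss in _patterns(missing):
        if not miss.any():
            continue
        o = ~miss
        m_idx = np.flatnonzero(miss)
        if o.any():
            s_oo = sigma[np.ix_(o, o)]
            s_mo = sigma[np.ix_(miss, o)]
            beta = _ridge_solve(s_oo, s_mo.T)
            cond_mean = mu[miss] + (X[np.ix_(rows, o)] - mu[o]) @ beta
            cond_cov = sigma[np.ix_(miss, miss)] - s_mo @ beta
        else:
            cond_mean = np.tile(mu[miss], (len(rows), 1))
            cond_cov = sigma[np.ix_(miss, miss)]
        vals = cond_mean
        if stochastic:
            root = _psd_sqrt(cond_cov)
            vals = vals + rng.standard_normal(cond_mean.shape) @ root.T
        out[np.ix_(rows, m_idx)] = vals
    return out


class EMImputer(BaseImputer):
    """Multivariate-normal EM imputer.

    Parameters
    ----------
    tol : float
        Maximum relative parameter change declaring convergence.
    max_iter : int
        Iteration cap.
    stochastic : bool
        Add conditional-normal residuals to the conditional means.
    random_state : int or None
        Seed for the residual draws.

    Attributes
    ----------
    mean_, covariance_ : fitted MVN parameters.
    loglik_trace_ : observed-data log-likelihood per iteration
        (non-decreasing).
    n_iter_, converged_ : EM diagnostics.
    """

    def __init__(
        self,
        tol: float = 1e-4,
        max_iter: int = 1000,
        stochastic: bool = True,
        random_state: int | None = None,
    ):
        self.tol = tol
        self.max_iter = max_iter
        self.stochastic = stochastic
        self.random_state = random_state

    def _fit(self, X: np.ndarray) -> None:
        params = em_fit(X, tol=self.tol, max_iter=self.max_iter)
        self.params_ = params
        self.mean_ = params.mu
        self.covariance_ = params.sigma
        self.loglik_trace_ = params.loglik_trace
        self.n_iter_ = params.n_iter
        self.converged_ = params.converged

    def _transform(self, X: np.ndarray) -> np.ndarray:
        return em_impute(
            X, self.params_, stochastic=self.stochastic, seed=self.random_state
        )
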