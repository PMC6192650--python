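"""MTAG-style per-trait estimator used as a head-to-head comparator.

MTAG (multi-trait analysis of GWAS) improves the effect estimate of each
individual trait by borrowing strength from genetically correlated traits.
With Omega = var(beta_j) the K x K variance of marginal effects and
Sigma_bhat the sampling covariance, the trait-k estimate solves the moment
equation E[beta_hat - (omega_k / omega_kk) * beta_k] = 0 and has the closed
form

    beta_MTAG_k = (a' beta_hat) / (a' omega_k / omega_kk),
    a = A^{-1} omega_k / omega_kk,
    A = Omega - omega_k omega_k' / omega_kk + Sigma_bhat,

where omega_k is the k-th column of Omega and omega_kk its k-th diagonal
entry. Omega is taken as mean(l)/M * Sigma_g, consistent with
E[beta beta' | l] = l * Sigma_g / M.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = ["mtag_weights", "mtag_zscores", "omega_from_sigma_g", "MTAG"]


def omega_from_sigma_g(sigma_g: np.ndarray, mean_ld_score: float, M: int) -> np.ndarray:
    """Variance of marginal effects: Omega = mean(l)/M * Sigma_g."""
    return np.asarray(sigma_g, float) * mean_ld_score / M


def mtag_weights(
    omega: np.ndarray, sigma_bhat: np.ndarray, k: int
) -> tuple[np.ndarray, float]:
    """Weight vector and normalizer of the trait-k MTAG estimator.

    Returns ``(a, d)`` such that beta_MTAG_k = (a' beta_hat) / d with
    a = A^{-1} omega_k / omega_kk and d = a' omega_k / omega_kk.
    """
    omega = np.atleast_2d(np.asarray(omega, float))
    sigma_bhat = np.atleast_2d(np.asarray(sigma_bhat, float))
    K = omega.shape[0]
    if not 0 <= k < K:
        raise IndexError(f"trait index {k} out of range for K={K}")
    wk = omega[:, k]
    wkk = omega[k, k]
    if wkk <= 0:
        raise ValueError("trait has zero genetic variance (omega_kk = 0)")
    g = wk / wkk
    A = omega - np.outer(wk, wk) / wkk + sigma_bhat
    a = np.linalg.solve(A, g)
    d = float(a @ g)
    return a, d


def mtag_zscores(
    beta_hat: np.ndarray, omega: np.ndarray, sigma_bhat: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trait MTAG z-statistics and two-sided p-values for every SNP.

    z = (a' beta_hat) / sqrt(a' Sigma_bhat a); the estimator's normalizer
    cancels between the point estimate and its standard error.
    """
    B = np.atleast_2d(np.asarray(beta_hat, float))
    K = B.shape[1]
    sigma_bhat = np.asarray(sigma_bhat, float)
    W = np.column_stack([mtag_weights(omega, sigma_bhat, k)[0] for k in range(K)])
    denom = np.sqrt(np.einsum("ik,ij,jk->k", W, sigma_bhat, W))
    Z = (B @ W) / denom
    P = 2.0 * stats.norm.sf(np.abs(Z))
    return Z, P


class MTAG(TransformerMixin, BaseEstimator):
    """Moment-based multi-trait estimator producing per-trait test statistics.

    Shares input conventions with :class:`hipokit.core.HIPO`: ``fit`` fixes
    Omega (from ``sigma_g`` with the mean LD score scale) and Sigma_bhat;
    ``transform`` maps M x K standardized effect estimates to per-trait MTAG
    z-scores.
    """

    def __init__(self, sigma_g=None, sigma_bhat=None, mean_ld_score=1.0, n_snps=None):
        self.sigma_g = sigma_g
        self.sigma_bhat = sigma_bhat
        self.mean_ld_score = mean_ld_score
        self.n_snps = n_snps

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_features=1)
        if self.sigma_g is None or self.sigma_bhat is None:
            raise ValueError("MTAG requires sigma_g and sigma_bhat")
        M = self.n_snps if self.n_snps is not None else X.shape[0]
        self.omega_ = omega_from_sigma_g(self.sigma_g, self.mean_ld_score, M)
        self.sigma_bhat_ = np.asarray(self.sigma_bhat, float)
        K = self.omega_.shape[0]
        self.weights_ = np.column_stack(
            [mtag_weights(self.omega_, self.sigma_bhat_, k)[0] for k in range(K)]
        )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "weights_")
        X = check_array(X)
        Z, _ = mtag_zscores(X, self.omega_, self.sigma_bhat_)
        return Z

    def pvalues(self, X):
        check_is_fitted(self, "weights_")
        X = check_array(X)
        _, P = mtag_zscores(X, self.omega_, self.sigma_bhat_)
        return P
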