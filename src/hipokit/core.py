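"""Heritability-informed power optimization (HIPO).

Given the genetic covariance Sigma_g and the sampling covariance Sigma_bhat of
standardized per-SNP effect estimates across K traits, HIPO finds weight
vectors c_1, ..., c_K that successively maximize the average non-centrality
parameter (NCP) of the association chi-square statistic,

    max_c  c' Sigma_g c   subject to  c' Sigma_bhat c = 1,

with each later component additionally Sigma_bhat-orthogonal to the earlier
ones. The solution is the eigensystem of S Sigma_g S with
S = Sigma_bhat^{-1/2}: the eigenvalues are the per-component average NCPs up
to the common scale factor mean(l)/M, and c_k = S u_k.

Each SNP is then tested along component k with
z_{j,k} = c_k' beta_hat_j / sqrt(c_k' Sigma_bhat c_k), a standard normal
under the global null of no association with any trait.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .ldscore import LDScoreSet, estimate_covariances

__all__ = [
    "HipoComponents",
    "hipo_decompose",
    "component_zscores",
    "average_ncp",
    "HIPO",
]


@dataclass
class HipoComponents:
    """HIPO weight vectors (columns of ``C``) and their eigenvalues.

    Invariants: C' Sigma_bhat C = I (each component has unit sampling variance
    and the components are mutually Sigma_bhat-orthogonal); eigenvalues are
    sorted non-increasing and equal c_k' Sigma_g c_k.
    """

    C: np.ndarray
    eigenvalues: np.ndarray
    traits: list[str]

    @property
    def n_traits(self) -> int:
        return self.C.shape[0]

    def component_names(self) -> list[str]:
        return [f"HIPO-D{k + 1}" for k in range(self.n_traits)]


def _inv_sqrt_sym(A: np.ndarray, rcond: float = 1e-12) -> np.ndarray:
    """Symmetric inverse square root via eigen-decomposition.

    Eigenvalues below ``rcond`` times the largest are treated as zero, which
    makes the matrix effectively singular and is reported as such.
    """
    A = 0.5 * (A + np.asarray(A).T)
    vals, vecs = np.linalg.eigh(A)
    cutoff = rcond * np.max(np.abs(vals))
    if np.any(vals <= cutoff):
        raise np.linalg.LinAlgError(
            "Sigma_bhat is singular or not positive definite; apply PSD repair "
            "(see ldscore.repair_psd) before decomposing"
        )
    return (vecs / np.sqrt(vals)) @ vecs.T


def _fix_signs(C: np.ndarray) -> np.ndarray:
    """Scale each column so its largest-magnitude entry is positive."""
    idx = np.argmax(np.abs(C), axis=0)
    signs = np.sign(C[idx, np.arange(C.shape[1])])
    signs[signs == 0] = 1.0
    return C * signs


def hipo_decompose(
    sigma_g: np.ndarray,
    sigma_bhat: np.ndarray,
    traits: list[str] | None = None,
) -> HipoComponents:
    """Solve the constrained average-NCP maximization by eigen-decomposition.

    Computes S = Sigma_bhat^{-1/2}, eigen-decomposes W = S Sigma_g S and maps
    eigenvectors back through c_k = S u_k, ordered by eigenvalue descending.
    """
    sigma_g = np.atleast_2d(np.asarray(sigma_g, float))
    sigma_bhat = np.atleast_2d(np.asarray(sigma_bhat, float))
    K = sigma_g.shape[0]
    if K == 0:
        raise ValueError("empty covariance matrices")
    if sigma_g.shape != (K, K) or sigma_bhat.shape != (K, K):
        raise ValueError("sigma_g and sigma_bhat must be square with equal dimension")
    if not np.allclose(sigma_g, sigma_g.T, atol=1e-8):
        raise ValueError("sigma_g must be symmetric")
    if not np.allclose(sigma_bhat, sigma_bhat.T, atol=1e-8):
        raise ValueError("sigma_bhat must be symmetric")

    S = _inv_sqrt_sym(sigma_bhat)
    W = S @ (0.5 * (sigma_g + sigma_g.T)) @ S
    vals, vecs = np.linalg.eigh(0.5 * (W + W.T))
    order = np.argsort(vals)[::-1]  # stable for ties after the eigh ordering
    C = _fix_signs(S @ vecs[:, order])
    traits = list(traits) if traits is not None else [f"trait{k + 1}" for k in range(K)]
    return HipoComponents(C=C, eigenvalues=vals[order], traits=traits)


def component_zscores(
    beta_hat: np.ndarray,
    components: HipoComponents,
    sigma_bhat: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP z-statistics and two-sided p-values along each HIPO component.

    ``beta_hat`` is the M x K matrix of standardized effect estimates. The
    denominator sqrt(c_k' Sigma_bhat c_k) equals 1 under the normalization but
    is computed explicitly so that unnormalized weight vectors also work.
    """
    B = np.atleast_2d(np.asarray(beta_hat, float))
    C = components.C
    if B.shape[1] != C.shape[0]:
        raise ValueError(
            f"panel has {B.shape[1]} traits but components were built for {C.shape[0]}"
        )
    denom = np.sqrt(np.einsum("ik,ij,jk->k", C, np.asarray(sigma_bhat, float), C))
    Z = (B @ C) / denom
    P = 2.0 * stats.norm.sf(np.abs(Z))
    return Z, P


def average_ncp(eigenvalues: np.ndarray, mean_ld_score: float, M: int) -> np.ndarray:
    """Average NCP per component: eigenvalue times mean LD score over M."""
    if M <= 0:
        raise ValueError("M must be positive")
    return np.asarray(eigenvalues, float) * mean_ld_score / M


class HIPO(TransformerMixin, BaseEstimator):
    """Multi-trait association test maximizing average chi-square NCP.

    A transformer over M x K matrices of standardized per-SNP effect
    estimates. ``fit`` obtains the genetic covariance ``Sigma_g`` and sampling
    covariance ``Sigma_bhat`` — either supplied directly (e.g. simulation
    truth) or estimated by cross-trait LD-score regression from z-scores —
    and solves the constrained eigenproblem. ``transform`` maps effect
    estimates to per-component z-scores.

    Parameters
    ----------
    sigma_g, sigma_bhat : optional K x K arrays
        Known covariances; when given, ``fit`` skips LDSC estimation.
    ld_scores : optional length-M array
        Per-SNP LD scores, required when covariances are estimated.
    n_samples : optional length-K array
        Per-trait (effective) sample sizes, required for estimation.
    n_snps : optional int
        Total SNP count M backing the LDSC slope scale; defaults to the
        number of rows seen in ``fit``.

    Attributes
    ----------
    components_ : (K, K) array, rows are weight vectors sorted by eigenvalue.
    eigenvalues_ : (K,) array, average NCP up to the mean(l)/M scale.
    avg_ncp_ : (K,) array, eigenvalues scaled by mean(l)/M (when l is known).
    sigma_g_, sigma_bhat_ : the covariances actually used.
    """

    def __init__(
        self,
        sigma_g=None,
        sigma_bhat=None,
        ld_scores=None,
        n_samples=None,
        n_snps=None,
    ):
        self.sigma_g = sigma_g
        self.sigma_bhat = sigma_bhat
        self.ld_scores = ld_scores
        self.n_samples = n_samples
        self.n_snps = n_snps

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_features=1)
        M = self.n_snps if self.n_snps is not None else X.shape[0]
        mean_l = None
        if self.sigma_g is not None and self.sigma_bhat is not None:
            self.sigma_g_ = np.asarray(self.sigma_g, float)
            self.sigma_bhat_ = np.asarray(self.sigma_bhat, float)
            if self.ld_scores is not None:
                mean_l = float(np.mean(self.ld_scores))
        else:
            if self.ld_scores is None or self.n_samples is None:
                raise ValueError(
                    "either supply sigma_g and sigma_bhat, or ld_scores and "
                    "n_samples for LD-score regression"
                )
            N = np.asarray(self.n_samples, float)
            Z = X * np.sqrt(N)  # standardized effects -> z-scores
            cov = estimate_covariances(Z, N, LDScoreSet(np.asarray(self.ld_scores)), M=M)
            self.covariances_ = cov
            self.sigma_g_ = cov.sigma_g
            self.sigma_bhat_ = cov.sigma_bhat
            mean_l = float(np.mean(self.ld_scores))
        comps = hipo_decompose(self.sigma_g_, self.sigma_bhat_)
        self.hipo_components_ = comps
        self.components_ = comps.C.T
        self.eigenvalues_ = comps.eigenvalues
        self.n_features_in_ = X.shape[1]
        if mean_l is not None:
            self.avg_ncp_ = average_ncp(comps.eigenvalues, mean_l, M)
        return self

    def transform(self, X):
        """Map standardized effect estimates to per-component z-scores."""
        check_is_fitted(self, "components_")
        X = check_array(X)
        Z, _ = component_zscores(X, self.hipo_components_, self.sigma_bhat_)
        return Z

    def pvalues(self, X):
        """Two-sided p-values along each component."""
        check_is_fitted(self, "components_")
        X = check_array(X)
        _, P = component_zscores(X, self.hipo_components_, self.sigma_bhat_)
        return P
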