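"""LD scores and cross-trait LD-score regression.

This module turns a reference LD panel (block-diagonal genotype correlation
matrices) into per-SNP LD scores, and estimates, for every pair of traits,

* the genetic covariance ``Sigma_g`` from the regression *slope* of z-score
  products on LD scores, and
* the sampling covariance ``Sigma_bhat`` of the standardized effect estimates
  from the regression *intercept* (which captures confounding on the diagonal
  and sample overlap x phenotypic correlation off the diagonal).

The regression of z_jk * z_jl on l_j follows the standard two-pass weighting
scheme: a preliminary unweighted fit provides per-trait heritabilities, which
feed a heteroskedasticity weight, multiplied by a 1/l_j over-counting weight.
Standard errors come from a delete-one block jackknife over contiguous SNP
blocks and are reported for diagnostics only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "LDPanel",
    "LDScoreSet",
    "LdscPairFit",
    "CovarianceSet",
    "compute_ld_scores",
    "ldsc_pair",
    "estimate_covariances",
    "repair_psd",
    "read_ld_scores",
    "write_ld_scores",
]


@dataclass
class LDPanel:
    """Block-diagonal LD reference: genotype correlations within blocks.

    Parameters
    ----------
    snps : DataFrame with columns ``snp_id``, ``chrom``, ``pos_bp``, ``maf``,
        one row per SNP in panel order.
    blocks : list of square correlation matrices; their sizes partition the
        SNP index. Correlation between SNPs in different blocks is zero.
    window_bp : neighborhood radius used when accumulating LD scores.
    """

    snps: pd.DataFrame
    blocks: list[np.ndarray]
    window_bp: int = 1_000_000

    def __post_init__(self) -> None:
        sizes = [b.shape[0] for b in self.blocks]
        if sum(sizes) != len(self.snps):
            raise ValueError("block sizes do not partition the SNP index")
        for b in self.blocks:
            if b.ndim != 2 or b.shape[0] != b.shape[1]:
                raise ValueError("each LD block must be square")
            if not np.allclose(np.diag(b), 1.0, atol=1e-8):
                raise ValueError("LD blocks must have unit diagonal")
            if np.abs(b).max() > 1 + 1e-8:
                raise ValueError("|r| must not exceed 1")
        bounds = np.concatenate([[0], np.cumsum(sizes)])
        self._starts = bounds[:-1]
        self.block_index = np.repeat(np.arange(len(sizes)), sizes)
        self.block_offset = np.arange(len(self.snps)) - self._starts[self.block_index]

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def block_slice(self, b: int) -> slice:
        start = self._starts[b]
        return slice(start, start + self.blocks[b].shape[0])

    def r(self, i: int, j: int) -> float:
        """Genotype correlation between panel SNPs ``i`` and ``j`` (0 across blocks)."""
        bi, bj = self.block_index[i], self.block_index[j]
        if bi != bj:
            return 0.0
        blk = self.blocks[bi]
        return float(blk[self.block_offset[i], self.block_offset[j]])

    def r2(self, i: int, j: int) -> float:
        return self.r(i, j) ** 2


@dataclass
class LDScoreSet:
    """Per-SNP LD scores l_j = sum of squared correlations within the window."""

    l: np.ndarray

    @property
    def mean_l(self) -> float:
        return float(np.mean(self.l))


def compute_ld_scores(
    panel: LDPanel, adjusted: bool = False, n_ref: int | None = None
) -> LDScoreSet:
    """Sum squared genotype correlations of each SNP with its window neighbours.

    With ``adjusted=True`` the small-sample unbiased estimator
    r~² = r² − (1 − r²)/(n_ref − 2) is accumulated instead of the raw r².
    """
    if panel.n_snps == 0:
        raise ValueError("empty LD panel")
    if adjusted:
        if n_ref is None or n_ref <= 2:
            raise ValueError("adjusted LD scores require n_ref > 2")
    pos = panel.snps["pos_bp"].to_numpy()
    l = np.empty(panel.n_snps)
    for b, R in enumerate(panel.blocks):
        sl = panel.block_slice(b)
        p = pos[sl]
        within = np.abs(p[:, None] - p[None, :]) <= panel.window_bp
        r2 = R**2
        if adjusted:
            r2 = r2 - (1.0 - r2) / (n_ref - 2)
        l[sl] = np.sum(np.where(within, r2, 0.0), axis=1)
    return LDScoreSet(l=l)


@dataclass
class LdscPairFit:
    """One bivariate LDSC fit: slope mapped to genetic covariance, plus intercept."""

    rho_g: float
    intercept: float
    slope: float
    se_rho_g: float
    se_intercept: float
    n_snps: int


def _jackknife_wls(x: np.ndarray, y: np.ndarray, w: np.ndarray, n_blocks: int):
    """Delete-one-block jackknife SEs for a weighted regression of y on [1, x]."""
    m = len(y)
    n_blocks = min(n_blocks, m)
    X = np.column_stack([np.ones(m), x])
    edges = np.linspace(0, m, n_blocks + 1).astype(int)
    A_blocks = np.empty((n_blocks, 2, 2))
    b_blocks = np.empty((n_blocks, 2))
    for i in range(n_blocks):
        sl = slice(edges[i], edges[i + 1])
        Xw = X[sl] * w[sl, None]
        A_blocks[i] = Xw.T @ X[sl]
        b_blocks[i] = Xw.T @ y[sl]
    A = A_blocks.sum(axis=0)
    b = b_blocks.sum(axis=0)
    thetas = np.empty((n_blocks, 2))
    for i in range(n_blocks):
        thetas[i] = np.linalg.solve(A - A_blocks[i], b - b_blocks[i])
    mean = thetas.mean(axis=0)
    var = (n_blocks - 1) / n_blocks * np.sum((thetas - mean) ** 2, axis=0)
    return np.sqrt(var)


def ldsc_pair(
    zk: np.ndarray,
    zl: np.ndarray,
    l: np.ndarray,
    Nk: float,
    Nl: float,
    M: int | None = None,
    min_snps: int = 200,
    n_jackknife_blocks: int = 200,
) -> LdscPairFit:
    """Regress z_jk * z_jl on LD scores; slope -> genetic covariance, intercept as-is.

    The slope s of E[z_k z_l] = sqrt(Nk*Nl)/M * rho_g * l_j + intercept maps to
    rho_g = s * M / sqrt(Nk*Nl). For k == l this yields the SNP heritability and
    the univariate intercept.
    """
    zk = np.asarray(zk, float)
    zl = np.asarray(zl, float)
    l = np.asarray(l, float)
    if not (len(zk) == len(zl) == len(l)):
        raise ValueError("zk, zl and l must have equal length")
    if len(zk) < min_snps:
        raise ValueError(f"need at least {min_snps} SNPs for LD-score regression")
    if np.ptp(l) < 1e-12:
        raise ValueError("degenerate LD scores: no variation to regress on")
    M = M if M is not None else len(l)

    y = zk * zl
    X = sm.add_constant(l)

    # pass 1: unweighted univariate fits give the heritabilities for the weights
    h2k = np.clip(sm.OLS(zk**2, X).fit().params[1] * M / Nk, 0.0, 1.0)
    h2l = np.clip(sm.OLS(zl**2, X).fit().params[1] * M / Nl, 0.0, 1.0)

    # pass 2: heteroskedasticity weight x 1/l over-counting weight
    lw = np.maximum(l, 1.0)
    w = 1.0 / (lw * (1.0 + Nk * h2k * lw / M) * (1.0 + Nl * h2l * lw / M))
    fit = sm.WLS(y, X, weights=w).fit()
    intercept, slope = fit.params

    se_int, se_slope = _jackknife_wls(l, y, w, n_jackknife_blocks)
    scale = M / np.sqrt(Nk * Nl)
    return LdscPairFit(
        rho_g=float(slope * scale),
        intercept=float(intercept),
        slope=float(slope),
        se_rho_g=float(se_slope * scale),
        se_intercept=float(se_int),
        n_snps=len(y),
    )


def repair_psd(
    A: np.ndarray, eps: float = 0.0, rescale_diag: bool = False
) -> tuple[np.ndarray, float]:
    """Clip eigenvalues below ``eps`` and reconstruct; optionally restore the diagonal.

    Returns the repaired matrix and the largest absolute eigenvalue change.
    """
    A = 0.5 * (A + A.T)
    vals, vecs = np.linalg.eigh(A)
    clipped = np.maximum(vals, eps)
    out = (vecs * clipped) @ vecs.T
    if rescale_diag:
        d_old = np.diag(A).copy()
        d_new = np.diag(out)
        ratio = np.where((d_old > 0) & (d_new > 0), d_old / np.where(d_new > 0, d_new, 1.0), 1.0)
        s = np.sqrt(ratio)
        out = out * np.outer(s, s)
    return 0.5 * (out + out.T), float(np.max(np.abs(clipped - vals)))


@dataclass
class CovarianceSet:
    """Estimated genetic covariance, LDSC intercepts and sampling covariance.

    ``sigma_bhat[k, l] = intercept[k, l] / sqrt(N_k * N_l)`` on the standardized
    effect scale; it is constant across SNPs.
    """

    sigma_g: np.ndarray
    intercept: np.ndarray
    sigma_bhat: np.ndarray
    N: np.ndarray
    M: int
    traits: list[str]
    se_sigma_g: np.ndarray | None = None
    se_intercept: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "traits": self.traits,
            "sigma_g": self.sigma_g.tolist(),
            "intercept": self.intercept.tolist(),
            "sigma_bhat": self.sigma_bhat.tolist(),
            "N": np.asarray(self.N, float).tolist(),
            "M": int(self.M),
        }
        if self.se_sigma_g is not None:
            payload["se_sigma_g"] = self.se_sigma_g.tolist()
        if self.se_intercept is not None:
            payload["se_intercept"] = self.se_intercept.tolist()
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CovarianceSet":
        d = json.loads(text)
        return cls(
            sigma_g=np.array(d["sigma_g"]),
            intercept=np.array(d["intercept"]),
            sigma_bhat=np.array(d["sigma_bhat"]),
            N=np.array(d["N"]),
            M=int(d["M"]),
            traits=list(d["traits"]),
            se_sigma_g=np.array(d["se_sigma_g"]) if "se_sigma_g" in d else None,
            se_intercept=np.array(d["se_intercept"]) if "se_intercept" in d else None,
        )


def estimate_covariances(
    Z: np.ndarray,
    N: Sequence[float],
    ld: LDScoreSet,
    M: int | None = None,
    traits: Sequence[str] | None = None,
    repair_tolerance: float = 0.05,
    min_snps: int = 200,
) -> CovarianceSet:
    """Run bivariate LDSC over all trait pairs and assemble the covariance set.

    ``Z`` is the M x K matrix of per-SNP z-scores; ``N`` the per-trait sample
    sizes. Both Sigma_g and the intercept matrix are symmetrized and repaired
    to be PSD (Sigma_g clipped at 0; Sigma_bhat clipped at 1e-8 with the
    diagonal rescaled back), with pre-repair copies kept in ``metadata``.
    """
    Z = np.atleast_2d(np.asarray(Z, float))
    K = Z.shape[1]
    N = np.asarray(N, float)
    if N.shape != (K,):
        raise ValueError("N must have one entry per trait")
    M = M if M is not None else Z.shape[0]
    traits = list(traits) if traits is not None else [f"trait{k + 1}" for k in range(K)]

    sigma_g = np.empty((K, K))
    intercept = np.empty((K, K))
    se_g = np.empty((K, K))
    se_int = np.empty((K, K))
    for k in range(K):
        for m in range(k, K):
            fit = ldsc_pair(Z[:, k], Z[:, m], ld.l, N[k], N[m], M, min_snps=min_snps)
            sigma_g[k, m] = sigma_g[m, k] = fit.rho_g
            intercept[k, m] = intercept[m, k] = fit.intercept
            se_g[k, m] = se_g[m, k] = fit.se_rho_g
            se_int[k, m] = se_int[m, k] = fit.se_intercept

    meta: dict = {"sigma_g_raw": sigma_g.copy(), "intercept_raw": intercept.copy()}
    sigma_g_rep, dg = repair_psd(sigma_g, eps=0.0)
    intercept_rep, di = repair_psd(intercept, eps=1e-8, rescale_diag=True)
    if max(dg, di) > repair_tolerance:
        meta["repair_warning"] = (
            f"PSD repair moved an eigenvalue by {max(dg, di):.3g} "
            f"(tolerance {repair_tolerance})"
        )
    sigma_bhat = intercept_rep / np.sqrt(np.outer(N, N))
    return CovarianceSet(
        sigma_g=sigma_g_rep,
        intercept=intercept_rep,
        sigma_bhat=sigma_bhat,
        N=N,
        M=M,
        traits=traits,
        se_sigma_g=se_g,
        se_intercept=se_int,
        metadata=meta,
    )


def write_ld_scores(path, panel: LDPanel, ld: LDScoreSet) -> None:
    """Write LD scores in the de-facto delimited format (CHR, SNP, BP, L2)."""
    df = pd.DataFrame(
        {
            "CHR": panel.snps["chrom"].to_numpy(),
            "SNP": panel.snps["snp_id"].to_numpy(),
            "BP": panel.snps["pos_bp"].to_numpy(),
            "L2": ld.l,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_ld_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=r"\s+")
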