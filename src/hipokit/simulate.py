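"""Direct simulation of multi-trait GWAS summary statistics.

Rather than simulating genotypes and phenotypes at biobank scale, summary
statistics are generated directly from the model

    beta_hat_j = beta_j + v_j + e_j,

where beta_j are marginal genetic effects (LD-weighted mixtures of sparse
joint effects), v_j is an i.i.d. per-SNP population-stratification
perturbation, and e_j is estimation error with the exact joint law
N(0, R (x) Sigma_e) over SNPs and traits — R the block-diagonal LD matrix and

    Sigma_e[k, l] = N_kl / (N_k N_l) * cov(y_k, y_l)

the sampling covariance induced by sample sizes, pairwise sample overlap
N_kl and phenotypic covariance. Because R is block diagonal, the Kronecker
law factorizes over LD blocks and is sampled exactly as
E_b = L_b G Lambda' with L_b L_b' = R_b and Lambda Lambda' = Sigma_e.

Everything needed for validation is tracked: the causal sets, joint and
marginal effects, and the stratification draws.

Preset covariance structures for two study settings (four blood-lipid traits
and three psychiatric disorders, both estimated from consortium data) are
provided, along with the stratification scale 7.35e-8 whose per-SNP variance
is about 25% of the per-SNP heritability when the largest trait heritability
is 0.35 over 1.2 million SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .ldscore import LDPanel

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "SimulatedStudy",
    "make_ld_panel",
    "draw_joint_effects",
    "marginal_effects",
    "error_covariance",
    "draw_errors",
    "draw_errors_from_genotypes",
    "draw_stratification",
    "simulate_sumstats",
    "equicorrelation",
    "lipid_config",
    "psychiatric_config",
    "LIPID_TRAITS",
    "LIPID_SIGMA_G_PATTERN",
    "LIPID_SIGMA_Y",
    "PSYCH_TRAITS",
    "PSYCH_SIGMA_G_PATTERN",
    "PSYCH_SIGMA_Y",
    "STRAT_VARIANCE",
]

# Genetic covariance patterns (scaled so the largest diagonal entry becomes
# h2max) and phenotypic covariance matrices estimated from consortium GWAS.
LIPID_TRAITS = ["LDL", "HDL", "TG", "TC"]
LIPID_SIGMA_G_PATTERN = np.array(
    [
        [0.87, -0.04, 0.30, 0.85],
        [-0.04, 1.00, -0.62, 0.18],
        [0.30, -0.62, 0.93, 0.30],
        [0.85, 0.18, 0.30, 0.95],
    ]
)
LIPID_SIGMA_Y = np.array(
    [
        [1.00, -0.10, 0.21, 0.86],
        [-0.10, 1.00, -0.36, 0.12],
        [0.21, -0.36, 1.00, 0.32],
        [0.86, 0.12, 0.32, 1.00],
    ]
)
PSYCH_TRAITS = ["ASD", "BIP", "SCZ"]
PSYCH_SIGMA_G_PATTERN = np.array(
    [
        [0.69, 0.02, 0.12],
        [0.02, 0.88, 0.63],
        [0.12, 0.63, 1.00],
    ]
)
PSYCH_SIGMA_Y = np.array(
    [
        [1.00, 0.01, 0.00],
        [0.01, 1.00, 0.01],
        [0.00, 0.01, 1.00],
    ]
)

#: Per-SNP stratification variance scale used in the reference simulations.
STRAT_VARIANCE = 7.35e-8


def equicorrelation(K: int, rho: float = 0.5) -> np.ndarray:
    """K x K matrix with unit diagonal and constant off-diagonal ``rho``."""
    return (1.0 - rho) * np.eye(K) + rho * np.ones((K, K))


@dataclass
class SimulationConfig:
    """Study conditions for one simulated multi-trait GWAS.

    ``sigma_g_pattern`` is rescaled so its largest diagonal entry equals
    ``h2max``; genetic correlations are preserved. ``n_overlap[k, l]`` is the
    number of subjects shared between studies k and l (``None`` means all
    traits are measured on the same subjects). ``causal_overlap`` is the
    fraction of causal SNPs shared across traits (1.0 = identical causal
    sets). ``causal_variance_m`` fixes the denominator of the per-causal-SNP
    effect variance Sigma_g / m; by default it equals ``m_causal`` so the
    summed heritability matches diag(Sigma_g), while scaled-down runs can pin
    it at a reference count to hold per-SNP variance components fixed.
    """

    sigma_g_pattern: np.ndarray
    sigma_y: np.ndarray
    h2max: float
    N: np.ndarray
    M: int
    m_causal: int
    traits: list[str] = field(default_factory=list)
    n_overlap: np.ndarray | None = None
    causal_overlap: float = 1.0
    sigma_v: np.ndarray | None = None
    causal_variance_m: int | None = None
    window_bp: int = 1_000_000
    r2_min: float = 0.01
    ld_block_size: int = 50
    ld_decay: float | tuple[float, float] = (0.1, 0.9)
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        self.sigma_g_pattern = np.atleast_2d(np.asarray(self.sigma_g_pattern, float))
        self.sigma_y = np.atleast_2d(np.asarray(self.sigma_y, float))
        self.N = np.broadcast_to(np.asarray(self.N, float), (self.K,)).copy()
        if not self.traits:
            self.traits = [f"trait{k + 1}" for k in range(self.K)]
        if self.m_causal > self.M:
            raise ValueError("m_causal cannot exceed M")
        if not 0.0 <= self.causal_overlap <= 1.0:
            raise ValueError("causal_overlap must lie in [0, 1]")
        if self.n_overlap is not None:
            self.n_overlap = np.asarray(self.n_overlap, float)
            if np.any(self.n_overlap > np.minimum.outer(self.N, self.N) + 1e-9):
                raise ValueError("n_overlap[k, l] cannot exceed min(N_k, N_l)")
        if self.sigma_v is not None:
            self.sigma_v = np.atleast_2d(np.asarray(self.sigma_v, float))

    @property
    def K(self) -> int:
        return self.sigma_g_pattern.shape[0]

    @property
    def sigma_g(self) -> np.ndarray:
        """Genetic covariance: pattern scaled so max heritability = h2max."""
        return self.sigma_g_pattern * (self.h2max / np.max(np.diag(self.sigma_g_pattern)))

    def to_dict(self) -> dict:
        d = {
            "traits": self.traits,
            "sigma_g_pattern": self.sigma_g_pattern.tolist(),
            "sigma_y": self.sigma_y.tolist(),
            "h2max": self.h2max,
            "N": self.N.tolist(),
            "M": self.M,
            "m_causal": self.m_causal,
            "causal_overlap": self.causal_overlap,
            "causal_variance_m": self.causal_variance_m,
            "window_bp": self.window_bp,
            "r2_min": self.r2_min,
            "ld_block_size": self.ld_block_size,
            "ld_decay": list(self.ld_decay)
            if isinstance(self.ld_decay, tuple)
            else self.ld_decay,
            "maf_range": list(self.maf_range),
            "seed": self.seed,
        }
        if self.n_overlap is not None:
            d["n_overlap"] = self.n_overlap.tolist()
        if self.sigma_v is not None:
            d["sigma_v"] = self.sigma_v.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("sigma_g_pattern", "sigma_y", "N", "n_overlap", "sigma_v"):
            if key in d and d[key] is not None:
                d[key] = np.asarray(d[key], float)
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        if "ld_decay" in d and isinstance(d["ld_decay"], list):
            d["ld_decay"] = tuple(d["ld_decay"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def lipid_config(h2max: float = 0.35, N: float = 100_000, M: int = 100_000,
                 causal_fraction: float = 0.01, stratification: bool = False,
                 seed: int = 0, **kwargs) -> SimulationConfig:
    """Four-trait blood-lipid setting (LDL, HDL, TG, TC), complete overlap."""
    sigma_v = STRAT_VARIANCE * equicorrelation(4, 0.5) if stratification else None
    return SimulationConfig(
        sigma_g_pattern=LIPID_SIGMA_G_PATTERN,
        sigma_y=LIPID_SIGMA_Y,
        h2max=h2max,
        N=np.full(4, float(N)),
        M=M,
        m_causal=int(round(causal_fraction * M)),
        traits=list(LIPID_TRAITS),
        sigma_v=sigma_v,
        seed=seed,
        **kwargs,
    )


def psychiatric_config(h2max: float = 0.35, N: float = 100_000, M: int = 100_000,
                       causal_fraction: float = 0.01, stratification: bool = False,
                       seed: int = 0, **kwargs) -> SimulationConfig:
    """Three-trait psychiatric setting (ASD, BIP, SCZ), complete overlap."""
    sigma_v = STRAT_VARIANCE * equicorrelation(3, 0.5) if stratification else None
    return SimulationConfig(
        sigma_g_pattern=PSYCH_SIGMA_G_PATTERN,
        sigma_y=PSYCH_SIGMA_Y,
        h2max=h2max,
        N=np.full(3, float(N)),
        M=M,
        m_causal=int(round(causal_fraction * M)),
        traits=list(PSYCH_TRAITS),
        sigma_v=sigma_v,
        seed=seed,
        **kwargs,
    )


@dataclass
class TruthSet:
    """Ground truth of a simulated study, for power and type-I evaluation."""

    causal: dict[str, np.ndarray]
    beta_joint: np.ndarray
    beta_marginal: np.ndarray
    strat: np.ndarray

    @property
    def null_mask(self) -> np.ndarray:
        """SNPs with zero marginal genetic effect for every trait."""
        return ~np.any(self.beta_marginal != 0.0, axis=1)


@dataclass
class SimulatedStudy:
    """Simulated summary statistics plus full truth tracking."""

    panel: LDPanel
    beta_hat: np.ndarray
    z: np.ndarray
    se: np.ndarray
    sigma_e: np.ndarray
    truth: TruthSet
    config: SimulationConfig

    @property
    def traits(self) -> list[str]:
        return self.config.traits

    def standardized_effects(self) -> np.ndarray:
        """Effects on the z/sqrt(N) scale expected by HIPO/MTAG."""
        return self.z / np.sqrt(self.config.N)

    def write(self, out_dir) -> None:
        """One summary-statistics file per trait, plus truth and config files."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        snps = self.panel.snps
        alleles_a1 = np.full(len(snps), "A")
        alleles_a2 = np.full(len(snps), "G")
        for k, trait in enumerate(self.traits):
            df = pd.DataFrame(
                {
                    "SNP": snps["snp_id"],
                    "CHR": snps["chrom"],
                    "BP": snps["pos_bp"],
                    "A1": alleles_a1,
                    "A2": alleles_a2,
                    "BETA": self.beta_hat[:, k],
                    "SE": self.se[k],
                    "Z": self.z[:, k],
                    "N": self.config.N[k],
                    "FRQ": snps["maf"],
                }
            )
            df.to_csv(out / f"{trait}.sumstats.txt", sep="\t", index=False)
        truth = pd.DataFrame(
            {"SNP": snps["snp_id"], "CHR": snps["chrom"], "BP": snps["pos_bp"]}
        )
        for k, trait in enumerate(self.traits):
            truth[f"BETA_JOINT_{trait}"] = self.truth.beta_joint[:, k]
            truth[f"BETA_MARGINAL_{trait}"] = self.truth.beta_marginal[:, k]
        truth.to_csv(out / "truth.txt", sep="\t", index=False)
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(self.config.to_dict(), fh)


def _ar1(size: int, rho: float) -> np.ndarray:
    idx = np.arange(size)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def make_ld_panel(
    n_blocks: int,
    block_size: int,
    decay_rate: float | tuple[float, float] | Sequence[float] = (0.1, 0.9),
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int | np.random.Generator = 0,
    window_bp: int = 1_000_000,
    spacing_bp: int = 5_000,
) -> LDPanel:
    """Synthetic block-diagonal LD panel with AR(1) within-block correlation.

    Blocks are laid out across chromosomes 1-22 with gaps larger than
    ``window_bp`` so that inter-block LD and window overlap are both exactly
    zero; within a block r_{jj'} = rho**|j - j'|, positive definite by
    construction for |rho| < 1. ``decay_rate`` may be a scalar (one rho for
    every block), a ``(low, high)`` pair (per-block rho drawn uniformly,
    emulating the heterogeneous LD across loci that gives real panels a
    broad LD-score distribution), or one value per block.
    """
    if block_size < 1:
        raise ValueError("block_size must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if np.isscalar(decay_rate):
        rhos = np.full(n_blocks, float(decay_rate))
    elif isinstance(decay_rate, tuple):
        lo, hi = decay_rate
        rhos = rng.uniform(lo, hi, size=n_blocks)
    else:
        rhos = np.asarray(decay_rate, float)
        if len(rhos) != n_blocks:
            raise ValueError("need one decay rate per block")
    if np.any(np.abs(rhos) >= 1.0):
        raise ValueError("AR(1) decay rate must satisfy |rho| < 1")
    blocks = [_ar1(block_size, float(r)) for r in rhos]
    M = n_blocks * block_size
    chrom = np.empty(M, dtype=int)
    pos = np.empty(M, dtype=int)
    per_chrom_next = {}
    for b in range(n_blocks):
        c = b % 22 + 1
        start = per_chrom_next.get(c, 1)
        sl = slice(b * block_size, (b + 1) * block_size)
        chrom[sl] = c
        pos[sl] = start + spacing_bp * np.arange(block_size)
        per_chrom_next[c] = int(pos[sl][-1] + window_bp + spacing_bp + 1)
    snps = pd.DataFrame(
        {
            "snp_id": [f"rs{i + 1}" for i in range(M)],
            "chrom": chrom,
            "pos_bp": pos,
            "maf": rng.uniform(maf_range[0], maf_range[1], size=M),
        }
    )
    return LDPanel(snps=snps, blocks=blocks, window_bp=window_bp)


def draw_joint_effects(
    config: SimulationConfig,
    panel: LDPanel,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Sparse joint effects: causal rows i.i.d. N(0, Sigma_g / m).

    With ``causal_overlap < 1`` each trait keeps a shared core of causal SNPs
    plus trait-specific picks; non-causal entries of a row are zeroed.
    """
    M, K = config.M, config.K
    beta_j = np.zeros((M, K))
    m = config.m_causal
    if m == 0:
        return beta_j, {t: np.array([], dtype=int) for t in config.traits}
    m_den = config.causal_variance_m if config.causal_variance_m else m

    if config.causal_overlap >= 1.0:
        idx = np.sort(rng.choice(M, size=m, replace=False))
        causal = {t: idx for t in config.traits}
        union = idx
    else:
        n_shared = int(round(config.causal_overlap * m))
        pool = rng.permutation(M)
        shared = pool[:n_shared]
        rest = pool[n_shared:]
        causal = {}
        offset = 0
        for t in config.traits:
            own = rest[offset : offset + (m - n_shared)]
            offset += m - n_shared
            if offset > len(rest):
                raise ValueError("not enough SNPs for disjoint causal sets")
            causal[t] = np.sort(np.concatenate([shared, own]))
        union = np.sort(np.unique(np.concatenate(list(causal.values()))))

    L = np.linalg.cholesky(config.sigma_g / m_den + 1e-18 * np.eye(K))
    draws = rng.standard_normal((len(union), K)) @ L.T
    beta_j[union] = draws
    if config.causal_overlap < 1.0:
        keep = np.zeros((M, K), dtype=bool)
        for k, t in enumerate(config.traits):
            keep[causal[t], k] = True
        beta_j[~keep] = 0.0
    return beta_j, causal


def marginal_effects(
    beta_joint: np.ndarray,
    panel: LDPanel,
    window_bp: int = 1_000_000,
    r2_min: float = 0.01,
) -> np.ndarray:
    """LD-weighted mixture: beta_j = sum over neighbours of beta^(J)_{j'} r_{jj'}.

    The neighbourhood holds SNPs within ``window_bp`` whose r-squared with j
    exceeds ``r2_min``; the SNP itself is always included.
    """
    beta_joint = np.asarray(beta_joint, float)
    out = np.zeros_like(beta_joint)
    pos = panel.snps["pos_bp"].to_numpy()
    for b, R in enumerate(panel.blocks):
        sl = panel.block_slice(b)
        if not np.any(beta_joint[sl]):
            continue
        p = pos[sl]
        mask = (R**2 > r2_min) & (np.abs(p[:, None] - p[None, :]) <= window_bp)
        np.fill_diagonal(mask, True)
        out[sl] = np.where(mask, R, 0.0) @ beta_joint[sl]
    return out


def error_covariance(
    sigma_y: np.ndarray,
    N: np.ndarray,
    n_overlap: np.ndarray | None = None,
) -> np.ndarray:
    """Sampling covariance Sigma_e[k, l] = N_kl / (N_k N_l) * cov(y_k, y_l).

    ``n_overlap=None`` means complete overlap: N_kl = min(N_k, N_l), so the
    diagonal is always Sigma_y[k, k] / N_k.
    """
    sigma_y = np.atleast_2d(np.asarray(sigma_y, float))
    N = np.asarray(N, float)
    if n_overlap is None:
        n_overlap = np.minimum.outer(N, N)
    n_overlap = np.asarray(n_overlap, float)
    return n_overlap / np.outer(N, N) * sigma_y


def _psd_factor(A: np.ndarray, jitter: float = 1e-10) -> np.ndarray:
    """Lower factor with L L' = A, tolerating PSD (rank-deficient) input."""
    A = np.atleast_2d(np.asarray(A, float))
    try:
        return np.linalg.cholesky(A + jitter * np.trace(A) / len(A) * np.eye(len(A)))
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh(0.5 * (A + A.T))
        if np.min(vals) < -1e-8 * max(np.max(vals), 1.0):
            raise ValueError("covariance matrix is not positive semi-definite")
        return vecs * np.sqrt(np.clip(vals, 0.0, None))


def draw_errors(
    panel: LDPanel,
    sigma_e: np.ndarray,
    rng: np.random.Generator,
    jitter: float = 1e-10,
) -> np.ndarray:
    """Exact sample from N(0, R (x) Sigma_e) with block-diagonal R.

    Per block b: E_b = L_b G Lambda' with L_b L_b' = R_b, Lambda Lambda' =
    Sigma_e, G i.i.d. standard normal; blocks independent.
    """
    sigma_e = np.atleast_2d(np.asarray(sigma_e, float))
    K = sigma_e.shape[0]
    if not np.any(sigma_e):
        return np.zeros((panel.n_snps, K))
    Lam = _psd_factor(sigma_e, jitter=0.0)
    out = np.empty((panel.n_snps, K))
    chol_cache: dict[int, np.ndarray] = {}
    for b, R in enumerate(panel.blocks):
        Lb = chol_cache.get(id(R))
        if Lb is None:
            Lb = np.linalg.cholesky(R + jitter * np.eye(len(R)))
            chol_cache[id(R)] = Lb
        G = rng.standard_normal((len(R), K))
        out[panel.block_slice(b)] = Lb @ G @ Lam.T
    return out


def draw_errors_from_genotypes(
    genotypes: np.ndarray,
    sigma_y: np.ndarray,
    N: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Resampling-mode error draw from a user-supplied genotype matrix.

    Simulates null phenotypes y ~ N(0, Sigma_y) for the n reference subjects,
    runs one-SNP-at-a-time regressions on standardized genotypes, and scales
    each trait's coefficients by sqrt(n / N_k) so the result follows the
    target error law with the reference panel's empirical LD.
    """
    X = np.asarray(genotypes, float)
    n = X.shape[0]
    Xs = (X - X.mean(axis=0)) / np.maximum(X.std(axis=0), 1e-12)
    Y = rng.standard_normal((n, len(N))) @ _psd_factor(sigma_y, jitter=0.0).T
    beta_null = Xs.T @ Y / n
    return beta_null * np.sqrt(n / np.asarray(N, float))


def draw_stratification(
    sigma_v: np.ndarray | None,
    M: int,
    rng: np.random.Generator,
    K: int | None = None,
) -> np.ndarray:
    """I.i.d. per-SNP stratification perturbations v_j ~ N(0, Sigma_v)."""
    if sigma_v is None:
        return np.zeros((M, K if K is not None else 1))
    sigma_v = np.atleast_2d(np.asarray(sigma_v, float))
    if not np.any(sigma_v):
        return np.zeros((M, sigma_v.shape[0]))
    return rng.standard_normal((M, sigma_v.shape[0])) @ _psd_factor(sigma_v).T


def simulate_sumstats(
    config: SimulationConfig, panel: LDPanel | None = None
) -> SimulatedStudy:
    """Compose effects, stratification and errors into one simulated study.

    Deterministic given ``config.seed``; the panel, effect, error and
    stratification draws use independent sub-streams of the master seed so
    each component can be regenerated on its own.
    """
    ss = np.random.SeedSequence(config.seed)
    s_panel, s_eff, s_err, s_strat = (np.random.default_rng(c) for c in ss.spawn(4))
    if panel is None:
        if config.M % config.ld_block_size:
            raise ValueError("M must be a multiple of ld_block_size")
        panel = make_ld_panel(
            n_blocks=config.M // config.ld_block_size,
            block_size=config.ld_block_size,
            decay_rate=config.ld_decay,
            maf_range=config.maf_range,
            seed=s_panel,
            window_bp=config.window_bp,
        )
    elif panel.n_snps != config.M:
        raise ValueError("panel size does not match config.M")

    beta_joint, causal = draw_joint_effects(config, panel, s_eff)
    beta_marg = marginal_effects(beta_joint, panel, config.window_bp, config.r2_min)
    sigma_e = error_covariance(config.sigma_y, config.N, config.n_overlap)
    e = draw_errors(panel, sigma_e, s_err)
    v = draw_stratification(config.sigma_v, config.M, s_strat, K=config.K)
    beta_hat = beta_marg + v + e
    se = np.sqrt(np.diag(sigma_e))
    z = np.divide(beta_hat, se, out=np.zeros_like(beta_hat), where=se > 0)
    truth = TruthSet(causal=causal, beta_joint=beta_joint, beta_marginal=beta_marg, strat=v)
    return SimulatedStudy(
        panel=panel, beta_hat=beta_hat, z=z, se=se, sigma_e=sigma_e,
        truth=truth, config=config,
    )
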