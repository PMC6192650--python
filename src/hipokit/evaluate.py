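"""Post-processing and evaluation of association scans.

Fixed-effect meta-analysis as the single-trait comparator, greedy LD
clumping of significant SNPs into independent loci, novel-locus calling
against a reference scan, and the genome-wide diagnostics used to judge
calibration and power: per-threshold type-I error over truly-null SNPs, the
genomic-control factor lambda_GC, mean chi-square, and QQ coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ldscore import LDPanel
from .simulate import TruthSet

__all__ = [
    "Locus",
    "meta_z",
    "clump",
    "novel_loci",
    "classify_true_loci",
    "type1_error",
    "lambda_gc_mean_chisq",
    "bonferroni_threshold",
    "qq_data",
    "loci_table",
]

#: Median of the 1-df chi-square distribution, the null reference for lambda_GC.
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))

GENOME_WIDE_P = 5e-8


@dataclass
class Locus:
    """An independent association locus found by greedy clumping."""

    lead_idx: int
    snp_id: str
    chrom: int
    pos_bp: int
    p: float
    members: list[int] = field(default_factory=list)
    source: str = ""


def meta_z(beta_hat: np.ndarray, se: Sequence[float]) -> np.ndarray:
    """Inverse-variance fixed-effect meta-analysis z-score per SNP.

    z_meta = sum_k w_k beta_k / sqrt(sum_k w_k^2 s_k^2) with w_k = 1/s_k^2,
    the no-overlap fixed-effect form; reduces to the single-trait z at K=1.
    """
    B = np.atleast_2d(np.asarray(beta_hat, float))
    se = np.asarray(se, float)
    w = 1.0 / se**2
    return (B @ w) / np.sqrt(np.sum(w**2 * se**2))


def clump(
    pvals: np.ndarray,
    panel: LDPanel,
    p_thresh: float = GENOME_WIDE_P,
    r2_thresh: float = 0.1,
    dist_bp: int = 500_000,
    source: str = "",
) -> list[Locus]:
    """Greedy significance-ordered clumping into independent loci.

    Repeatedly takes the smallest remaining p-value at or below ``p_thresh``
    as a lead SNP and absorbs every SNP with r^2 >= ``r2_thresh`` with the
    lead or within ``dist_bp`` of it (on the same chromosome); leads are
    returned in discovery order.
    """
    p = np.asarray(pvals, float)
    if len(p) != panel.n_snps:
        raise ValueError("p-values and panel are misaligned")
    chrom = panel.snps["chrom"].to_numpy()
    pos = panel.snps["pos_bp"].to_numpy()
    snp_id = panel.snps["snp_id"].to_numpy()

    sig = np.flatnonzero(p <= p_thresh)
    sig = sig[np.argsort(p[sig], kind="mergesort")]
    available = np.ones(panel.n_snps, dtype=bool)
    loci: list[Locus] = []
    for lead in sig:
        if not available[lead]:
            continue
        near = (chrom == chrom[lead]) & (np.abs(pos - pos[lead]) <= dist_bp)
        b = panel.block_index[lead]
        sl = panel.block_slice(b)
        in_ld = np.zeros(panel.n_snps, dtype=bool)
        r_row = panel.blocks[b][panel.block_offset[lead]]
        in_ld[sl] = r_row**2 >= r2_thresh
        absorb = (near | in_ld) & available
        members = [int(i) for i in np.flatnonzero(absorb & (p <= p_thresh))]
        available &= ~absorb
        loci.append(
            Locus(
                lead_idx=int(lead),
                snp_id=str(snp_id[lead]),
                chrom=int(chrom[lead]),
                pos_bp=int(pos[lead]),
                p=float(p[lead]),
                members=members,
                source=source,
            )
        )
    return loci


def novel_loci(
    candidates: Sequence[Locus],
    reference: Sequence[Locus],
    panel: LDPanel,
    dist_bp: int = 500_000,
    r2_thresh: float = 0.1,
) -> list[Locus]:
    """Candidate loci whose lead is far from AND in low LD with every reference lead.

    Novelty requires, against each reference lead, distance >= ``dist_bp``
    (automatically satisfied across chromosomes) and r^2 < ``r2_thresh``;
    failing either condition against any reference lead disqualifies.
    """
    out = []
    for cand in candidates:
        novel = True
        for ref in reference:
            same_chrom = cand.chrom == ref.chrom
            close = same_chrom and abs(cand.pos_bp - ref.pos_bp) < dist_bp
            high_ld = panel.r2(cand.lead_idx, ref.lead_idx) >= r2_thresh
            if close or high_ld:
                novel = False
                break
        if novel:
            out.append(cand)
    return out


def classify_true_loci(
    loci: Sequence[Locus],
    truth: TruthSet,
    panel: LDPanel,
    dist_bp: int = 500_000,
    r2_thresh: float = 0.1,
) -> dict:
    """Count loci whose lead tags a SNP with nonzero marginal effect.

    A locus is "true" iff its lead is within ``dist_bp`` (inclusive, same
    chromosome) of, or has r^2 >= ``r2_thresh`` with, any SNP whose marginal
    genetic effect is nonzero for some trait. The matching rule is echoed in
    the result for the report.
    """
    signal = np.flatnonzero(np.any(truth.beta_marginal != 0.0, axis=1))
    chrom = panel.snps["chrom"].to_numpy()
    pos = panel.snps["pos_bp"].to_numpy()
    sig_chrom = chrom[signal]
    sig_pos = pos[signal]
    n_true = 0
    flags = []
    for locus in loci:
        near = np.any(
            (sig_chrom == locus.chrom) & (np.abs(sig_pos - locus.pos_bp) <= dist_bp)
        )
        if not near:
            b = panel.block_index[locus.lead_idx]
            sl = panel.block_slice(b)
            r_row = panel.blocks[b][panel.block_offset[locus.lead_idx]]
            in_block = signal[(signal >= sl.start) & (signal < sl.stop)]
            near = bool(np.any(r_row[in_block - sl.start] ** 2 >= r2_thresh))
        flags.append(bool(near))
        n_true += bool(near)
    return {
        "n_loci": len(loci),
        "n_true": n_true,
        "n_false": len(loci) - n_true,
        "flags": flags,
        "rule": f"lead within {dist_bp} bp (inclusive) or r2 >= {r2_thresh} "
        "of any nonzero-marginal-effect SNP",
    }


def type1_error(
    pvals: np.ndarray | Sequence[np.ndarray],
    null_mask: np.ndarray | Sequence[np.ndarray],
    thresholds: Sequence[float] = (0.05, 0.01, 0.001),
) -> dict[float, float]:
    """Fraction of truly-null SNPs below each threshold, averaged over replicates.

    ``pvals`` and ``null_mask`` may be single arrays or per-replicate lists.
    """
    if isinstance(pvals, np.ndarray) and np.asarray(pvals).ndim == 1:
        pvals = [np.asarray(pvals)]
        null_mask = [np.asarray(null_mask)]
    rates = {float(t): [] for t in thresholds}
    for p, mask in zip(pvals, null_mask):
        p_null = np.asarray(p)[np.asarray(mask, bool)]
        if p_null.size == 0:
            raise ValueError("empty null SNP set")
        for t in thresholds:
            rates[float(t)].append(float(np.mean(p_null < t)))
    return {t: float(np.mean(v)) for t, v in rates.items()}


def lambda_gc_mean_chisq(z: np.ndarray) -> tuple[float, float]:
    """Genomic-control factor and mean chi-square of a z-score vector."""
    z = np.asarray(z, float)
    if z.size == 0:
        raise ValueError("empty z vector")
    chisq = z**2
    return float(np.median(chisq) / CHI2_1_MEDIAN), float(np.mean(chisq))


def bonferroni_threshold(n_traits: int, n_components: int) -> float:
    """Genome-wide threshold adjusted for testing traits plus HIPO components."""
    total = n_traits + n_components
    if n_traits < 0 or n_components < 0 or total < 1:
        raise ValueError("need a non-negative test count summing to at least 1")
    return GENOME_WIDE_P / total


def qq_data(pvals: np.ndarray) -> pd.DataFrame:
    """Expected vs observed -log10 p coordinates for a QQ plot."""
    p = np.sort(np.asarray(pvals, float))
    m = len(p)
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    observed = -np.log10(np.maximum(p, 1e-300))
    # most significant first for both columns
    return pd.DataFrame({"expected": expected, "observed": observed})


def loci_table(loci: Sequence[Locus], novel: Sequence[Locus] = ()) -> pd.DataFrame:
    """Delimited-friendly locus table (CHR, LEAD_SNP, BP, P, SOURCE, NOVEL)."""
    novel_ids = {l.lead_idx for l in novel}
    return pd.DataFrame(
        {
            "CHR": [l.chrom for l in loci],
            "LEAD_SNP": [l.snp_id for l in loci],
            "BP": [l.pos_bp for l in loci],
            "P": [l.p for l in loci],
            "SOURCE": [l.source for l in loci],
            "NOVEL": [l.lead_idx in novel_ids for l in loci],
        }
    )
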