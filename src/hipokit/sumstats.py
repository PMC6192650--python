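"""Reading, QC filtering and harmonization of GWAS summary statistics.

Per-trait association tables (one row per SNP: identifiers, alleles, effect
estimate / standard error or z-score, sample size) are cleaned with the
LD-Hub-style filters — outlier chi-square, the MHC region, low reference
minor-allele frequency, low per-SNP sample size, allele mismatches — then
intersected across traits and allele-oriented to a common reference into a
single M x K panel of z-scores and standardized effects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_COLUMNS",
    "SumstatTable",
    "MultiTraitPanel",
    "effective_sample_size",
    "read_sumstats",
    "qc_filter",
    "harmonize",
    "standardized_effects",
]

#: Default header-name mapping for delimited summary-statistics files.
DEFAULT_COLUMNS = {
    "SNP": "snp_id",
    "CHR": "chrom",
    "BP": "pos_bp",
    "A1": "allele_effect",
    "A2": "allele_other",
    "BETA": "beta_hat",
    "SE": "se",
    "Z": "z",
    "N": "n",
    "N_CASE": "n_case",
    "N_CONTROL": "n_control",
    "FRQ": "maf",
}

_VALID_ALLELES = frozenset("ACGT")
_AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}

# QC rule constants
CHISQ_MAX = 80.0
MHC_CHROM = 6
MHC_START, MHC_END = 26_000_000, 34_000_000  # inclusive
MAF_MIN = 0.05
N_QUANTILE = 0.90
N_QUANTILE_FACTOR = 0.67


def effective_sample_size(n_case: float, n_control: float) -> float:
    """Equivalent quantitative-trait N of a case-control GWAS.

    N_eff = N_case * N_control / (N_case + N_control); e.g. the trio-augmented
    autism study with 4949 cases and 5314 controls has N_eff ~= 2562.5.
    """
    if n_case <= 0 or n_control <= 0:
        raise ValueError("case and control counts must be positive")
    return n_case * n_control / (n_case + n_control)


@dataclass
class SumstatTable:
    """One trait's per-SNP association records.

    ``df`` carries the canonical columns snp_id, chrom, pos_bp, allele_effect,
    allele_other, beta_hat, se, z, n (and maf when available), is sorted by
    (chrom, pos_bp) and has unique snp_ids.
    """

    trait_id: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        if df["snp_id"].duplicated().any():
            raise ValueError(f"duplicate snp_id in table for {self.trait_id}")
        # reconstruct whichever of beta/z is missing from the other
        if "z" not in df or df["z"].isna().all():
            df["z"] = df["beta_hat"] / df["se"]
        if "beta_hat" not in df or df["beta_hat"].isna().all():
            df["beta_hat"] = df["z"] * df["se"]
        fill_z = df["z"].isna() & df["beta_hat"].notna() & df["se"].notna()
        df.loc[fill_z, "z"] = df.loc[fill_z, "beta_hat"] / df.loc[fill_z, "se"]
        fill_b = df["beta_hat"].isna() & df["z"].notna() & df["se"].notna()
        df.loc[fill_b, "beta_hat"] = df.loc[fill_b, "z"] * df.loc[fill_b, "se"]
        if (df["se"] <= 0).any():
            raise ValueError("standard errors must be positive")
        both = df["z"].notna() & df["beta_hat"].notna()
        mismatch = np.abs(df.loc[both, "z"] - df.loc[both, "beta_hat"] / df.loc[both, "se"])
        if (mismatch >= 1e-8 * np.maximum(1.0, np.abs(df.loc[both, "z"]))).any():
            raise ValueError("z and beta_hat/se disagree")
        if "maf" in df and df["maf"].notna().any():
            maf = df["maf"].dropna()
            if ((maf < 0) | (maf > 0.5)).any():
                raise ValueError("maf must lie in [0, 0.5]")
        self.df = df.sort_values(["chrom", "pos_bp"], kind="mergesort").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)


def read_sumstats(
    path,
    trait_id: str,
    column_map: Mapping[str, str] | None = None,
) -> SumstatTable:
    """Read a whitespace/tab-delimited summary-statistics file (gzip ok).

    ``column_map`` maps file headers to canonical names and defaults to
    :data:`DEFAULT_COLUMNS`; unknown columns are kept untouched. Case-control
    counts, when present without N, are folded into the effective sample size.
    """
    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=r"\s+", compression="infer")
    df = df.rename(columns={c: cmap[c] for c in df.columns if c in cmap})
    if "n" not in df.columns and {"n_case", "n_control"} <= set(df.columns):
        df["n"] = [
            effective_sample_size(a, b) for a, b in zip(df["n_case"], df["n_control"])
        ]
    for col in ("beta_hat", "z", "maf"):
        if col not in df.columns:
            df[col] = np.nan
    for col in ("allele_effect", "allele_other"):
        df[col] = df[col].str.upper()
    return SumstatTable(trait_id=trait_id, df=df)


def qc_filter(
    table: SumstatTable,
    reference: pd.DataFrame | None = None,
    n_quantile_factor: float = N_QUANTILE_FACTOR,
) -> tuple[SumstatTable, dict[str, int]]:
    """Apply the standard summary-statistics QC filters; log removals per rule.

    Removes records with (1) chi-square z^2 > 80, (2) position in the MHC
    region (chr6:26-34 Mb, inclusive), (3) reference MAF < 5%, (4) sample
    size below ``n_quantile_factor`` times the 90th percentile of N computed
    on the post-rule-1-3 table, (5) alleles that do not match the reference
    pair (allele swap allowed; missing reference entries logged separately).
    ``reference`` is a DataFrame indexed by snp_id with columns
    allele_effect, allele_other, maf; rules 3 and 5 are skipped without it.
    The operation is idempotent.
    """
    df = table.df
    log = {
        "chisq_gt_80": 0,
        "mhc_region": 0,
        "low_maf": 0,
        "low_sample_size": 0,
        "allele_mismatch": 0,
        "missing_in_reference": 0,
    }

    # strictly greater; small tolerance keeps chi-square exactly at the bound
    r1 = df["z"] ** 2 > CHISQ_MAX * (1 + 1e-12)
    r2 = (df["chrom"] == MHC_CHROM) & df["pos_bp"].between(MHC_START, MHC_END)
    if reference is not None:
        ref = reference.reindex(df["snp_id"])
        missing = ref["allele_effect"].isna().to_numpy()
        ref_maf = ref["maf"].to_numpy()
        r3 = (~missing) & (ref_maf < MAF_MIN)
        pair = [frozenset((a, b)) for a, b in zip(df["allele_effect"], df["allele_other"])]
        ref_pair = [
            frozenset((a, b)) if isinstance(a, str) else None
            for a, b in zip(ref["allele_effect"], ref["allele_other"])
        ]
        r5 = np.array(
            [rp is not None and p != rp for p, rp in zip(pair, ref_pair)]
        ) | np.array([not (p <= _VALID_ALLELES) for p in pair])
    else:
        missing = np.zeros(len(df), dtype=bool)
        r3 = np.zeros(len(df), dtype=bool)
        r5 = np.zeros(len(df), dtype=bool)

    early = r1.to_numpy() | r2.to_numpy() | np.asarray(r3)
    # rule 4 quantile on the table surviving rules 1-3
    surviving_n = df.loc[~early, "n"]
    n_cut = n_quantile_factor * surviving_n.quantile(N_QUANTILE) if len(surviving_n) else 0.0
    r4 = (df["n"] < n_cut).to_numpy()

    log["chisq_gt_80"] = int(r1.sum())
    log["mhc_region"] = int((r2 & ~r1).sum())
    log["low_maf"] = int((np.asarray(r3) & ~r1.to_numpy() & ~r2.to_numpy()).sum())
    drop123 = early
    log["low_sample_size"] = int((r4 & ~drop123).sum())
    log["missing_in_reference"] = int((missing & ~drop123 & ~r4).sum())
    drop = drop123 | r4 | missing
    log["allele_mismatch"] = int((np.asarray(r5) & ~drop).sum())
    drop = drop | np.asarray(r5)

    kept = df.loc[~drop].reset_index(drop=True)
    return SumstatTable(trait_id=table.trait_id, df=kept), log


@dataclass
class MultiTraitPanel:
    """Harmonized M x K panel of z-scores and standardized effects."""

    snps: pd.DataFrame
    Z: np.ndarray
    N: np.ndarray
    traits: list[str]
    ld_scores: np.ndarray | None = None
    log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.Z = np.atleast_2d(np.asarray(self.Z, float))
        if not np.all(np.isfinite(self.Z)):
            raise ValueError("panel z-scores must be finite")
        self.N = np.asarray(self.N, float)

    @property
    def B(self) -> np.ndarray:
        """Standardized effect estimates B = Z / sqrt(N)."""
        return standardized_effects(self.Z, self.N)

    @property
    def n_snps(self) -> int:
        return self.Z.shape[0]

    def write(self, path, log_path=None) -> None:
        out = self.snps.copy()
        for k, t in enumerate(self.traits):
            out[f"Z_{t}"] = self.Z[:, k]
        out.to_csv(path, sep="\t", index=False)
        if log_path is not None:
            with open(log_path, "w") as fh:
                json.dump(self.log, fh, indent=2, default=int)


def standardized_effects(Z: np.ndarray, N: Sequence[float]) -> np.ndarray:
    """Standardized-scale effects B_jk = Z_jk / sqrt(N_k); exact inverse of B*sqrt(N)."""
    N = np.asarray(N, float)
    if np.any(N <= 1):
        raise ValueError("sample sizes must exceed 1")
    return np.asarray(Z, float) / np.sqrt(N)


def harmonize(
    tables: Sequence[SumstatTable],
    reference: pd.DataFrame | None = None,
    drop_ambiguous: bool = True,
) -> MultiTraitPanel:
    """Intersect SNPs across traits and orient every record to reference alleles.

    A trait whose effect allele equals the reference *other* allele has its
    z and beta signs flipped. Without a reference the first table's alleles
    serve as the orientation target. Strand-ambiguous (A/T, C/G) pairs are
    dropped by default; SNPs with irreconcilable allele pairs are dropped and
    logged.
    """
    if not tables:
        raise ValueError("need at least one table")
    common = None
    for t in tables:
        ids = set(t.df["snp_id"])
        common = ids if common is None else common & ids
    if not common:
        raise ValueError("no SNPs shared by all traits")

    base = tables[0].df[tables[0].df["snp_id"].isin(common)]
    if reference is not None:
        ref = reference.reindex(base["snp_id"]).reset_index()
        ra1 = ref["allele_effect"].to_numpy(dtype=object)
        ra2 = ref["allele_other"].to_numpy(dtype=object)
        have = ~pd.isna(ra1)
        ref_a1 = np.where(have, ra1, base["allele_effect"].to_numpy()).astype(str)
        ref_a2 = np.where(have, ra2, base["allele_other"].to_numpy()).astype(str)
    else:
        ref_a1 = base["allele_effect"].to_numpy()
        ref_a2 = base["allele_other"].to_numpy()
    snps = pd.DataFrame(
        {
            "snp_id": base["snp_id"].to_numpy(),
            "chrom": base["chrom"].to_numpy(),
            "pos_bp": base["pos_bp"].to_numpy(),
            "allele_effect": ref_a1,
            "allele_other": ref_a2,
        }
    )

    keep = np.ones(len(snps), dtype=bool)
    dropped_ambiguous = 0
    if drop_ambiguous:
        amb = np.array(
            [frozenset((a, b)) in _AMBIGUOUS_PAIRS for a, b in zip(ref_a1, ref_a2)]
        )
        dropped_ambiguous = int(amb.sum())
        keep &= ~amb

    K = len(tables)
    Z = np.empty((len(snps), K))
    N = np.empty(K)
    irreconcilable = np.zeros(len(snps), dtype=bool)
    for k, t in enumerate(tables):
        sub = t.df.set_index("snp_id").reindex(snps["snp_id"])
        same = (sub["allele_effect"].to_numpy() == ref_a1) & (
            sub["allele_other"].to_numpy() == ref_a2
        )
        flipped = (sub["allele_effect"].to_numpy() == ref_a2) & (
            sub["allele_other"].to_numpy() == ref_a1
        )
        irreconcilable |= ~(same | flipped)
        Z[:, k] = np.where(flipped, -sub["z"].to_numpy(), sub["z"].to_numpy())
        N[k] = float(np.nanmedian(sub["n"].to_numpy()))
    keep &= ~irreconcilable

    order = np.lexsort((snps["pos_bp"].to_numpy(), snps["chrom"].to_numpy()))
    order = order[keep[order]]
    return MultiTraitPanel(
        snps=snps.iloc[order].reset_index(drop=True),
        Z=Z[order],
        N=N,
        traits=[t.trait_id for t in tables],
        log={
            "n_common": len(common),
            "dropped_ambiguous": dropped_ambiguous,
            "dropped_irreconcilable": int(irreconcilable.sum()),
        },
    )
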