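# Methods

## Model

For SNP j, let β̂ⱼ be the length-K vector of standardized marginal effect
estimates (genotypes and phenotypes scaled to unit variance) from one-SNP-
at-a-time GWAS of K traits, with β̂ⱼ | βⱼ ~ N(βⱼ, Σ_β̂). Joint (all-SNP)
effects are modeled as β⁽ᴶ⁾ⱼ ~ N(0, Σ_g/M); marginal effects are the
LD-weighted mixture βⱼ = Σ_{j′∈N(j)} β⁽ᴶ⁾_{j′} r_{jj′}, which gives
E[βⱼβⱼᵀ | lⱼ] = lⱼ Σ_g/M with lⱼ = Σ_{j′} r²_{jj′} the LD score. The
sampling covariance Σ_β̂ is constant across SNPs on the standardized scale
and equals the LDSC intercept matrix rescaled by 1/√(N_k N_l); its
off-diagonals capture sample overlap times phenotypic covariance. Binary
traits enter through the effective sample size N_case·N_control/(N_case+N_control).

The average NCP of the χ² test of the combination cᵀβ̂ is
E[δ] = (E[l]/M) · cᵀΣ_g c / cᵀΣ_β̂ c. Maximizing cᵀΣ_g c subject to
cᵀΣ_β̂ c = 1, then iterating under Σ_β̂-orthogonality, is solved by the
symmetric eigenproblem of W = S Σ_g S with S = Σ_β̂^(−1/2): components are
cₖ = S uₖ and the eigenvalues are the per-component average NCPs up to the
common factor E[l]/M. All K components are reported together with their
average NCPs so users can keep only dominant ones.

Per-SNP tests use z = cₖᵀβ̂ⱼ / √(cₖᵀΣ_β̂cₖ) against the standard normal.
These test the *global* null of no association with any trait; a
significant SNP is not attributed to an individual trait. The MTAG
comparator estimates trait-specific effects instead, via the moment
solution β̂_MTAG,k = (ωₖ/ω_kk)ᵀA⁻¹β̂ / ((ωₖ/ω_kk)ᵀA⁻¹ωₖ/ω_kk) with
A = Ω − ωₖωₖᵀ/ω_kk + Σ_β̂ and Ω = (E[l]/M)·Σ_g; its closed form is verified
in the tests against a root-finder on the moment equation.

## Estimation choices

* **LD-score regression.** z-score products regressed on LD scores; slope
  × M/√(N_kN_l) gives the genetic covariance entry, the intercept is kept
  as-is. Weights are the product of a 1/l over-counting term and the
  cross-trait heteroskedasticity term 1/[(1+N_k h²_k l/M)(1+N_l h²_l l/M)],
  with the h² plugged in from a preliminary unweighted pass. Standard
  errors come from a 200-block delete-one jackknife and are diagnostic
  only; they never enter the component weights. No annotation partitioning.
* **PSD repair.** Estimated Σ_g is clipped at eigenvalue 0; the intercept
  matrix at 1e-8 with its diagonal rescaled back, since the decomposition
  needs an invertible Σ_β̂ and a PSD Σ_g. Pre-repair matrices are kept in
  metadata, and users can bypass estimation entirely by supplying known
  covariances (as the simulation studies do).
* **Decomposition.** The inverse square root uses the symmetric
  eigen-decomposition (eigenvalues below 1e-12 of the largest → error
  directing the user to PSD repair), so the orthogonality constraints hold
  symmetrically. Sign convention: each component's largest-magnitude weight
  is positive. Equal eigenvalues keep the solver's stable order; any
  rotation within an eigenspace is statistically equivalent.

## Summary-statistics QC

Records are removed for: χ² > 80 (strictly; an epsilon guards the exact
boundary), MHC region chr6:26,000,000–34,000,000 inclusive, reference
MAF < 5%, N below 0.67 × the 90th percentile of N (computed on the table
surviving the first three rules, since this filter targets within-study
missingness), and allele pairs that do not match the reference (swaps
allowed; missing reference entries logged separately). Harmonization
intersects SNPs across traits, orients signs to the reference effect
allele, and drops palindromic (A/T, C/G) SNPs by default (configurable);
the QC pass is idempotent and harmonization is order-invariant given a
reference.

## Simulator

Summary statistics are generated directly as β̂ⱼ = βⱼ + vⱼ + eⱼ:

* **LD panel.** Block-diagonal AR(1) correlation blocks (default 50 SNPs,
  5 kb spacing) laid across chromosomes 1–22 with inter-block gaps larger
  than the 1 Mb window, so cross-block LD is exactly zero. Per-block decay
  rates are drawn uniformly from (0.1, 0.9) by default: real reference
  panels show strong LD heterogeneity across loci, and the resulting broad
  LD-score distribution is what identifies the LDSC regression; a single
  shared decay rate is available but leaves the regression poorly
  conditioned. Positive definite by construction.
* **Effects.** A causal fraction (default 1%) is drawn uniformly; causal
  rows of β⁽ᴶ⁾ are i.i.d. N(0, Σ_g/m) and marginal effects apply the LD
  mixture over neighbours within 1 Mb with r² > 0.01. The denominator m
  defaults to the causal count (total heritability = diag Σ_g); scaled-down
  calibration runs instead pin it at the reference count 12,000 so that
  per-causal-SNP variance — and hence every per-SNP variance component —
  matches the full-scale design. Causal sets are fully shared across traits
  by default, with fractional or disjoint sharing supported.
* **Errors.** e ~ N(0, R ⊗ Σ_e) with Σ_e[k,l] = N_kl/(N_kN_l)·cov(y_k,y_l)
  (complete overlap by default, N_kl = min(N_k,N_l)). Because R is block
  diagonal the Kronecker law factorizes and is sampled exactly per block as
  L_b G Λᵀ. A resampling mode over a user-supplied genotype matrix
  (null-phenotype regressions scaled by √(n/N)) is provided for fidelity
  studies against empirical LD. Per-block Cholesky uses a 1e-10 jitter.
* **Stratification.** vⱼ i.i.d. N(0, Σ_v); the reference scale
  7.35×10⁻⁸ × equicorrelation(0.5) makes per-SNP stratification ≈25% of the
  per-SNP heritability at h²max = 0.35 over 1.2M SNPs.
* **Determinism.** One master seed spawns independent sub-streams for
  panel, effects, errors and stratification, so identical seeds give
  bit-identical studies and components can be regenerated independently.

What the simulator does *not* emulate: minor-allele-frequency-dependent
architecture, in-sample LD estimation noise, imputation error, per-SNP
sample-size variation within a study, and long-range LD beyond the block
structure. Passing calibration tests therefore demonstrates correctness of
the statistical machinery under the stated model, not robustness to every
artifact of real summary data.

## Evaluation

Loci are formed by greedy significance-ordered clumping (PLINK-style):
smallest remaining p ≤ 5×10⁻⁸ becomes a lead; SNPs with r² ≥ 0.1 or within
0.5 Mb are absorbed (1 Mb sensitivity setting supported). A locus is novel
if its lead is both ≥0.5 Mb from and at r² < 0.1 with every reference lead
(conjunction). Truth matching for simulated power studies is configurable
and logged; the default calls a locus true when its lead is within 0.5 Mb
(inclusive) of, or in r² ≥ 0.1 with, any SNP of nonzero marginal effect.
λ_GC uses the χ²₁ median 0.4549; type-I error averages the per-replicate
fraction of truly-null SNPs (zero marginal effect for every trait) below
each threshold. Loci are counted per test and then merged through the
novelty rule, rather than pooling significant SNPs before clumping.

## Problem sizes and tolerances

Calibration studies run 20 replicates of 100K SNPs (120K for the 0.001
threshold, giving >100K null SNPs per replicate); power and
parameter-recovery studies use 50K SNPs at N = 100K. Monte-Carlo
tolerances are 3σ binomial bounds counting one effective draw per LD block
per replicate — deliberately conservative against within-block correlation
of test statistics. Analytic expectations for the stratified settings
(null variance 1 + cᵀΣ_v c after Σ_β̂ normalization) are computed in closed
form inside the tests and serve as the comparison point for the simulated
rates. Parameter recovery is asserted within 3 jackknife SEs.

## Known limitations

* Association along a component tests the global null only; trait
  attribution needs follow-up (e.g. the MTAG comparator).
* LDSC weighting follows the standard two-pass convention; alternative
  weighting or constrained-intercept variants are not implemented.
* The synthetic LD panel's block structure makes inter-block r² exactly
  zero; clumping distances interact with that structure more cleanly than
  they would with real LD.
* Sample sizes are assumed constant across SNPs within a study (after the
  QC missingness filter).
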