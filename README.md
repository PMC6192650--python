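# hipokit

Heritability-informed power optimization (HIPO) for multi-trait GWAS
summary statistics.

## The problem

Genetically correlated traits — blood lipid fractions, psychiatric
disorders, social-science phenotypes — share association signals that no
single-trait genome-wide scan uses efficiently. Given only per-trait GWAS
summary statistics (effect estimates β̂ⱼ, standard errors, sample sizes) for
K traits and an LD reference, hipokit finds the linear combinations of the
per-SNP effect estimates across traits that are *optimal for discovery*: the
weight vector **c** maximizing the average non-centrality parameter (NCP) of
the association χ² statistic,

```
max_c  cᵀ Σ̂_g c    subject to   cᵀ Σ̂_β̂ c = 1,
```

where Σ_g is the K×K genetic covariance matrix (SNP heritabilities on the
diagonal) and Σ_β̂ the sampling covariance of standardized effect estimates,
which absorbs sample-size differences and unknown sample overlap between
studies. Both matrices are estimated from summary statistics alone by
cross-trait LD-score regression (slopes → Σ_g, intercepts → Σ_β̂).
Successive components are Σ_β̂-orthogonal, so the solution is the
eigensystem of Σ_β̂^(−1/2) Σ_g Σ_β̂^(−1/2): eigenvalues are per-component
average NCPs up to the common scale E[l]/M, and each SNP is tested along
component k with z = cₖᵀβ̂ⱼ / √(cₖᵀΣ_β̂cₖ), standard normal under the global
null. HIPO generalizes inverse-SE-weighted meta-analysis (to which it
reduces when heritabilities are equal, genetic correlation is 1 and samples
do not overlap) and is compared head-to-head with the MTAG moment estimator,
which is also provided.

The package also contains the direct summary-statistics simulator used to
validate the method: marginal effects built from sparse joint effects mixed
through LD, estimation error drawn exactly from N(0, R ⊗ Σ_e) with
block-diagonal LD and overlap-aware Σ_e, and i.i.d. per-SNP population
stratification — with full truth tracking for type-I-error and power
studies.

## Worked example

Simulate a four-trait blood-lipid style study (h²max = 0.35, N = 100K,
50K SNPs, 1% causal), estimate the covariances by LD-score regression, and
scan along HIPO components:

```python
import numpy as np
from scipy import stats
from hipokit import (lipid_config, simulate_sumstats, compute_ld_scores,
                     HIPO, clump, novel_loci, lambda_gc_mean_chisq)

cfg = lipid_config(h2max=0.35, N=100_000, M=50_000, seed=1)
study = simulate_sumstats(cfg)
ld = compute_ld_scores(study.panel)

hipo = HIPO(ld_scores=ld.l, n_samples=cfg.N).fit(study.standardized_effects())
print("h2 estimates:", np.round(np.diag(hipo.sigma_g_), 3))
print("avg NCP     :", np.round(hipo.avg_ncp_, 3))

Z = hipo.transform(study.standardized_effects())
P = hipo.pvalues(study.standardized_effects())
print("HIPO-D1 mean chi2 = %.3f" % lambda_gc_mean_chisq(Z[:, 0])[1])

single = []
for k, t in enumerate(cfg.traits):
    pk = 2 * stats.norm.sf(np.abs(study.z[:, k]))
    single += clump(pk, study.panel, source=t)
d1 = clump(P[:, 0], study.panel, source="HIPO-D1")
print("HIPO-D1 loci:", len(d1),
      "| novel:", len(novel_loci(d1, single, study.panel)))
```

Output:

```
h2 estimates: [0.203 0.397 0.305 0.261]
avg NCP     : [2.258 1.122 0.591 0.352]
HIPO-D1 mean chi2 = 3.167
HIPO-D1 loci: 244 | novel: 2
```

The LDSC-estimated heritabilities bracket the generating values (true max
0.35 on HDL); the leading component's average NCP (2.26) — and its mean χ²
of 3.17 — exceed those of every individual trait (best single trait:
2.63), and clumping its p-values at 5×10⁻⁸ yields loci that no single-trait
scan found. When testing several traits plus components, use
`bonferroni_threshold(n_traits, n_components)` (e.g. 4 traits + 2
components → 8.3×10⁻⁹).

The same pipeline is scriptable from the shell via the `hipo-kit` console
tool (`munge`, `ldsc`, `hipo`, `mtag`, `simulate`, `evaluate` subcommands).

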