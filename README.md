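# fbcm — family-based Bayesian collapsing model for rare-variant association

`fbcm` tests whether the rare variants (MAF < 1%) in a gene are associated
with a quantitative trait, using nuclear families (offspring plus both
genotyped parents).  It is aimed at family-based sequencing studies where
population stratification would contaminate population-based burden tests
such as CMC or SKAT: association is read off the *transmission deviations*
within families, which stratification cannot produce.

## Model

For offspring *j* in family *i*, the genotypic score `G_ijk` (minor-allele
count at locus *k*) is decomposed into the Mendelian expectation given the
parents, `GE_ik = (GM_ik + GF_ik) / 2`, and the transmission deviation
`D_ijk = G_ijk − GE_ik`.  Because rare variants almost never deviate at
more than two loci in one individual (P ≈ 1.4% at 50 loci with carrier
probability 1%), each offspring is collapsed to its two rarest deviating
loci, indexed `r_ij` and `s_ij` (a zero "pseudolocus" with `GE = D = 0`
fills unused slots).  The trait is modelled hierarchically:

    y_ij = μ + β₁ (α_r D_ij,r + α_s D_ij,s)
             + β₂ (γ_r GE_i,r + γ_s GE_i,s) + φ_i + ε_ij

    φ_i ~ N(0, σ²_φ),  ε_ij ~ N(0, σ²_ε)
    α_k ~ Bern(p_k),  p_k ~ Beta(1, 1)     (γ_k, q_k analogous)
    β₁, β₂ ~ N(0, σ²_β),  σ²_β = 10⁴

The binary spike indicators α_k select which variants carry the shared
within-family effect β₁, so the model collapses a data-driven subset of
variants; γ_k and β₂ absorb effects acting through the between-family
component (stratification).  Inference on β₁ is therefore
stratification-resistant.  All full conditionals are conjugate and the
posterior is sampled by a JIT-compiled Gibbs sampler with multiple
dispersed chains and Gelman–Rubin diagnostics.

Gene-level evidence is the hybrid Bayes factor for the composite event
{ |β₁| > ε  and  Σ_k α_k > 0 }, the ratio of its (continuity-corrected)
posterior odds to its closed-form prior odds

    (1 − erf(x))(1 − 0.5^K) / (erf(x)(1 − 0.5^K) + 0.5^K),
    x = ε / (√2 σ_β),

with ε = 0.2 σ̂_ε from a pilot fit without genotype terms.  A gene is
called associated when BF > 2, a cutoff calibrated by simulation to hold
the type-I error below 0.005.  Variant-level evidence is each α_k's
marginal Bayes factor (prior odds exactly 1).

## Worked example

```python
import numpy as np
from fbcm import (SimulationConfig, simulate_dataset, FBCM, MCMCConfig,
                  estimate_sigma_eps_null, compute_epsilon)

config = SimulationConfig(n_families=300, n_variants=50, maf=0.005,
                          beta1=1.5, prop_causal=1.0, seed=1)
gene = simulate_dataset(config).collapse()
print(f"{gene.n_offspring} offspring, {gene.n_variants} rare variants, "
      f"{np.sum(gene.r > 0)} with a transmission deviation")

sigma_hat = estimate_sigma_eps_null(gene.y, None, gene.fam_index,
                                    MCMCConfig(iterations=2000, chains=1, seed=2))
eps = compute_epsilon(sigma_hat)
print(f"null residual SD = {sigma_hat:.3f}, epsilon = {eps:.3f}")

model = FBCM(iterations=5000, chains=2, random_state=3).fit(gene)
result = model.bayes_factors(eps)
print(f"gene BF = {result.gene_bf:.2f} ({result.label}), "
      f"effect size = {result.beta1_mean:.2f}, R-hat max = {model.rhat_max_:.3f}")
```

prints

```
600 offspring, 50 rare variants, 360 with a transmission deviation
null residual SD = 1.309, epsilon = 0.262
gene BF = 20.94 (strong), effect size = 1.76, R-hat max = 1.005
```

The gene's Bayes factor (20.9 ≫ 2) correctly flags the simulated
association; the effect size is the posterior mean of β₁ (see
`docs/methods.md` for why indicator selection biases it above the
generating value of 1.5 at these sample sizes); R-hat near 1 indicates
the two chains mixed.

Real studies enter through files instead of the simulator:

```bash
fbcm scan --vcf study.vcf --ped study.ped --pheno phenotypes.tsv \
          --genes genes.bed --out results/ --seed 1
```

which writes `genes.tsv` (one row per gene, sorted by BF), `variants.tsv`
(per-variant marginal BFs) and a Manhattan-ready TSV.  The phenotype TSV
holds repeated visit measurements; each individual is summarised by the
log of the highest measurement, with the age at that visit as a
covariate.  `fbcm simulate` and `fbcm power` expose the generator and the
replicated power / type-I-error harness.

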