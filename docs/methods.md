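# Methods

## Model

The package tests gene-level association between rare variants and a
quantitative trait in nuclear families.  Offspring genotypic scores are
split into a between-family component — the Mendelian expectation
`GE = (GM + GF)/2` given the two parental scores — and a within-family
component, the transmission deviation `D = G − GE ∈ [−1, 1]`.  By
construction E[D | parents] = 0, so the two components are orthogonal and
any systematic relation between D and the trait reflects transmission
disequilibrium, which population stratification cannot generate.

Because a rare-variant gene (MAF < 1%) almost never shows deviations at
more than two loci in one individual (for K = 50 independent loci at
carrier probability 1%, P(X > 2) ≈ 1.38% with X ~ Binomial(50, 0.01)),
each offspring is represented by at most two deviating loci: `r` is the
deviating locus with the smallest MAF, `s` the second smallest, and the
pseudolocus 0 (GE = D = 0) fills empty slots.  This keeps the design
fixed-width and the sampler linear in the number of offspring.

The hierarchical model is

    y_ij = μ + x_ij'c + β₁(α_r D_ij,r + α_s D_ij,s)
             + β₂(γ_r GE_i,r + γ_s GE_i,s) + φ_i + ε_ij,
    φ_i ~ N(0, σ²_φ),  ε_ij ~ N(0, σ²_ε),
    α_k ~ Bern(p_k), p_k ~ Beta(1,1);  γ_k ~ Bern(q_k), q_k ~ Beta(1,1);
    μ, c, β₁, β₂ ~ N(0, σ²_β);  σ²_φ, σ²_ε ~ Inv-Gamma(0.01, 0.01).

The binary indicator α_k declares variant k associated; the multiplicative
pairing of a shared effect β₁ with per-variant indicators is what makes
this a *collapsing* model — the collapsed set is chosen by the data rather
than fixed a priori.  γ and β₂ play the same role for the between-family
component, absorbing stratification-driven signal; the family effect φ_i
absorbs remaining shared environment.  The pseudolocus indicators α₀, γ₀
are structurally zero.  Covariates (e.g. age) enter as fixed linear terms
with the same vague normal prior; they are not part of the genotype
decomposition.

### Assumptions

- Both parents genotyped; offspring with any missing genotype in the
  gene, a missing phenotype or an ungenotyped parent are excluded for
  that gene.  Mendelian-impossible offspring are dropped with a warning.
- Diallelic loci; multi-allelic records must be split upstream.
- Gaussian trait given the predictors; exchangeable siblings.
- Loci approximately independent (an optional greedy LD-pruning pass,
  pairwise r² threshold, default off, can enforce a "representative SNP"
  selection; rare variants rarely show strong LD).

## Inference

Every full conditional is conjugate, so the sampler is pure Gibbs — exact
two-point updates for each α_k/γ_k using the likelihood ratio over the
offspring whose (r, s) reference that locus, Beta(1+ind, 2−ind) updates
for p_k/q_k, normal updates for the location parameters and family
effects, inverse-gamma for the variances.  The sweep is JIT-compiled
(numba) with a running residual vector refreshed every 512 sweeps to
bound floating-point drift; indicator-update logits are clipped at ±35
and inverse-gamma draws are guarded against underflow.  A sweep costs
O(N + K + #incidences), which is what makes genome-wide scans and
replicated calibration studies feasible on one CPU.

Defaults: 50,000 iterations, burn-in the first half (the burn-in fraction
is a package choice; diagnostics, not dogma, should confirm it), 3 chains,
no thinning, σ²_β = 10⁴.  Chain c starts from μ, β₁, β₂ ~ N(0,1)·(1+c),
indicators at 0 and variances at the sample variance of y, giving the
dispersed starts that the Gelman–Rubin statistic needs; each chain draws
its kernel seed from a spawned `SeedSequence`, so runs are exactly
reproducible given one master seed.  R-hat is the classic potential scale
reduction factor √(((n−1)/n·W + B/n)/W); it is reported for the
continuous scalar parameters.

### Bayes factors

Testing β₁ = 0 directly is meaningless for a continuous posterior, so the
gene-level test is the composite event {|β₁| > ε and Σα_k > 0} with
ε = 0.2·σ̂_ε, where σ̂_ε is the posterior-mean residual SD of a pilot fit
without genotype terms (intercept + covariates + family effect).  The
threshold exists because an arbitrarily small ε would amplify Monte-Carlo
error in tail-probability estimates.  The hybrid Bayes factor is the
posterior odds of the event over its closed-form prior odds
(1−erf(x))(1−0.5^K)/(erf(x)(1−0.5^K)+0.5^K), x = ε/(√2σ_β).

Two deliberate resolutions of ambiguities in this construction:

- **Sidedness.** The event uses |β₁| > ε on both sides of the Bayes
  factor, because the closed-form prior odds correspond to the two-sided
  tail of N(0, σ²_β); mixing a one-sided posterior event with a two-sided
  prior would bias every BF by a factor ≈ 2.
- **Joint vs marginal event.** The indicator condition Σα_k > 0 is kept
  in both posterior and prior.  Dropping it (a `joint=False` switch is
  provided) inflates BFs under the null whenever β₁ is prior-dominated.

Finite chains are handled with the continuity correction
P̂ = (m + 0.5)/(n + 1), which keeps all BFs finite and strictly monotone
in the event count.  Variant-level marginal BFs use the same correction
with prior odds exactly 1 (the Beta(1,1) marginal makes α_k ~ Bern(1/2)).
The decision cutoff BF > 2 is the simulation-calibrated default; Jeffreys
grades ("substantial" for 3–10, etc.) are attached as labels only.

### Degenerate inputs

A gene with no rare polymorphic variant is skipped before fitting; a gene
whose offspring show no transmission deviation raises a skip signal (GE
enters only through deviation-indexed loci, so such genes carry no
information about either β).  Monomorphic variants are excluded even
though "MAF < 1%" admits them: they cannot deviate and would inflate K in
the prior odds.  MAF ties in the (r, s) ranking break by genomic
position, then variant id, for determinism; ties in the per-individual
maximum phenotype across visits resolve to the earliest age.  Dosage
genotypes are used as given for MAF estimation and rounded to the nearest
integer in {0, 1, 2} for the model; columns with mean dosage/2 above 0.5
are flipped to the minor-allele convention and flagged.

## Synthetic data generator

The generator reproduces the calibration design: M = 300 families, 2
siblings each, K = 50 loci at MAF 0.005; parental scores Bern(2·MAF) per
locus (every carrier parent heterozygous), offspring by random Mendelian
transmission; a causal subset (proportion 0.2–1.0) acts on the trait
through β₁·(D×r); half the loci are neutral but stratification-associated
through β₂·(E×s) with β₂ = 0.5; sibling noise is bivariate normal with
covariance [[2, 1], [1, 2]] (shared variance 1 absorbed by φ, individual
variance 1 by ε, sibling correlation 0.5 under the null).  Stratified
loci are drawn from the non-causal complement when it is large enough
(they are meant to be neutral), overlapping only when the causal
proportion exceeds one half.

Seeding: a master seed spawns per-replicate `SeedSequence` children, and
within a replicate separate streams drive (a) indicator selection, (b)
genotypes, (c) phenotype noise, (d) the sampler.  Runs sharing a master
seed therefore share genotypes and noise across effect sizes, and the
causal set is a prefix of one shared permutation so causal sets are
nested across causal proportions — power comparisons are paired, which
is what makes small-replicate ordering checks stable.

What the generator does not emulate: LD between loci, multi-generation
pedigrees, ascertainment, genotyping error, missing data, non-Gaussian
traits.  Passing calibration tests on it therefore demonstrates internal
correctness of the machinery under the model's own assumptions, not
robustness to those real-data features.

## Problem sizes used by the test suite

The shipped checks use sizes chosen to finish on a single CPU while
keeping the binomial/Monte-Carlo error bars meaningful: 200 null
replicates at 5,000 iterations/2 chains for the type-I error check (an
exact binomial test against rate 0.005), 50 replicates per cell for the
power-ordering grid over β₁ ∈ {1, 1.5} × causal proportion
∈ {0.2, 0.6, 1.0}, 10⁷ draws for the Monte-Carlo prior-odds check, and
50 replicates for parameter recovery.  The full-scale versions (1,000
null replicates, 50,000 iterations, 3 chains) use the same code paths
with larger settings.

## Known limitations

- **Selection bias of the effect-size posterior.**  With free indicators
  the posterior mean of β₁ is biased away from zero whenever per-locus
  evidence is weak: at MAF 0.005 each locus is informed by only ~6
  deviating offspring, so α_k posteriors stay near 0.7 even when every
  locus is causal, and indicator configurations that drop ill-fitting
  loci support larger β₁.  The parameter-recovery check in the test
  suite quantifies this: with indicators clamped to 1 the 95% credible
  interval for β₁ has near-nominal coverage of the generating value,
  while the model-averaged posterior covers it in only about half the
  replicates.  The Gibbs kernel itself was validated exactly against
  brute-force enumeration of indicator configurations with analytic β₁
  integration, so this is a property of the model, not of the sampler.
  Reported "effect sizes" (posterior mean of β₁) should be read as
  evidence-weighted summaries, not unbiased estimates.
- The hybrid BF is conservative by construction at these settings: the
  prior odds of the event are large (σ_β = 100 puts almost all prior
  mass beyond ε), so BF > 2 demands a near-unanimous posterior event.
  That is what drives the very low null rejection rate.
- Binary traits (link functions) and sib-only decompositions for
  families with missing parents are out of scope.
- Gene assignment places a variant in every overlapping gene interval;
  no LD-aware assignment is attempted.
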