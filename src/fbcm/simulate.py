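"""Synthetic nuclear-family data generator and power / type-I-error harness.

The generator reproduces the calibration design used to tune the method:
M = 300 families of 2 siblings, K = 50 rare diallelic loci at MAF = 0.005,
parental scores drawn Bern(2*MAF) per locus (so a parent is at most a
heterozygous carrier), offspring genotypes by random Mendelian
transmission, a randomly chosen causal subset of loci acting through the
transmission deviations (effect beta1), half the loci neutral but
associated through population stratification acting through the expected
scores (effect beta2 = 0.5), and sibling noise from a bivariate normal
with covariance [[2, 1], [1, 2]].

What it does not emulate: linkage disequilibrium between loci,
multi-generation pedigrees, ascertainment, missing genotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bayes import compute_epsilon
from .errors import DimensionError
from .model import FBCM, MCMCConfig, estimate_sigma_eps_null
from .pedigree import CollapsedGene, FamilyGenotypes, collapse_gene

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SimulatedData",
    "ExperimentResult",
    "simulate_parents",
    "transmit",
    "simulate_phenotypes",
    "simulate_dataset",
    "run_experiment",
]


@dataclass
class SimulationConfig:
    """Study-design constants of the calibration simulation."""

    n_families: int = 300
    n_offspring: int = 2
    n_variants: int = 50
    maf: float = 0.005
    beta1: float = 0.0
    beta2: float = 0.5
    prop_causal: float = 0.2
    prop_stratified: float = 0.5
    sigma: tuple = ((2.0, 1.0), (1.0, 2.0))
    seed: int = 0

    def sigma_matrix(self) -> np.ndarray:
        s = np.asarray(self.sigma, dtype=np.float64)
        if s.shape != (2, 2) or s[0, 1] != s[1, 0]:
            raise ValueError("sigma must be a symmetric 2x2 matrix")
        return s


def simulate_parents(K: int, maf: float, rng: np.random.Generator):
    """Parental genotypic scores: independent Bern(2*MAF) per locus and
    parent, so every carrier parent is heterozygous."""
    if maf < 0 or 2.0 * maf > 1.0:
        raise ValueError("need 0 <= 2*maf <= 1")
    gm = (rng.random(K) < 2.0 * maf).astype(np.int64)
    gf = (rng.random(K) < 2.0 * maf).astype(np.int64)
    return gm, gf


def transmit(gm, gf, n_offspring: int, rng: np.random.Generator):
    """Offspring scores by random Mendelian transmission.

    A parent with score g transmits a minor allele with probability g/2:
    deterministic for homozygotes, a fair coin for heterozygotes.
    """
    gm = np.asarray(gm)
    gf = np.asarray(gf)
    K = gm.shape[0]
    tm = rng.random((n_offspring, K)) < gm[None, :] / 2.0
    tf = rng.random((n_offspring, K)) < gf[None, :] / 2.0
    return (tm.astype(np.int64) + tf.astype(np.int64))


def _noise_cov(sigma: np.ndarray, n_offspring: int) -> np.ndarray:
    """Exchangeable extension of the 2x2 sibling covariance to n siblings."""
    cov = np.full((n_offspring, n_offspring), sigma[0, 1])
    np.fill_diagonal(cov, sigma[0, 0])
    return cov


def simulate_phenotypes(D, E, rvec, svec, beta1, beta2, sigma, rng: np.random.Generator):
    """Sibling phenotypes for one family.

    Mean vector beta1 * (D @ r) + beta2 * (E @ s) — the causal loci act
    through the transmission deviations, the stratification loci through
    the family's expected scores — plus multivariate-normal noise with the
    exchangeable sibling covariance.
    """
    D = np.atleast_2d(np.asarray(D, dtype=np.float64))
    E = np.asarray(E, dtype=np.float64)
    rvec = np.asarray(rvec, dtype=np.float64)
    svec = np.asarray(svec, dtype=np.float64)
    if D.shape[1] != rvec.shape[0] or E.shape[0] != svec.shape[0]:
        raise DimensionError("indicator vectors do not match locus count")
    n = D.shape[0]
    cov = _noise_cov(np.asarray(sigma, dtype=np.float64), n)
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("sigma is not positive definite") from exc
    mean = beta1 * (D @ rvec) + beta2 * float(E @ svec)
    return mean + L @ rng.standard_normal(n)


@dataclass
class SimulatedData:
    """One replicate: raw families plus the true indicator vectors."""

    families: list
    causal: np.ndarray       # (K,) 0/1 causal indicator (acts on D)
    stratified: np.ndarray   # (K,) 0/1 stratification indicator (acts on GE)
    config: SimulationConfig

    def collapse(self, gene_id: str = "simulated_gene") -> CollapsedGene:
        cfg = self.config
        return collapse_gene(
            self.families,
            mafs=np.full(cfg.n_variants, cfg.maf),
            gene_id=gene_id,
        )


def _indicators(config: SimulationConfig, rng: np.random.Generator):
    K = config.n_variants
    n_causal = int(round(config.prop_causal * K))
    n_strat = int(round(config.prop_stratified * K))
    perm = rng.permutation(K)
    causal_idx = perm[:n_causal]
    complement = perm[n_causal:]
    if n_strat <= complement.shape[0]:
        strat_idx = rng.permutation(complement)[:n_strat]
    else:
        # stratified loci are meant to be neutral, but with a large causal
        # fraction the complement is too small; allow overlap for the rest
        deficit = n_strat - complement.shape[0]
        strat_idx = np.concatenate(
            [complement, rng.permutation(causal_idx)[:deficit]]
        )
        logger.debug(
            "stratified set overlaps causal set at %d loci (prop_causal=%.2f)",
            deficit, config.prop_causal,
        )
    causal = np.zeros(K)
    causal[causal_idx] = 1.0
    strat = np.zeros(K)
    strat[strat_idx] = 1.0
    return causal, strat


def simulate_dataset(config: SimulationConfig, seed=None) -> SimulatedData:
    """Generate one replicate of the family study.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``; it defaults
    to ``config.seed``.  Indicator draws, genotype draws and phenotype
    noise use separate child streams so that replicates generated with the
    same seed are maximally coupled across effect sizes (identical
    genotypes and noise) and across causal proportions (nested causal
    sets, since the causal set is a prefix of one shared permutation).
    """
    if seed is None:
        seed = config.seed
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ind_ss, geno_ss, noise_ss = ss.spawn(3)
    ind_rng = np.random.default_rng(ind_ss)
    geno_rng = np.random.default_rng(geno_ss)
    noise_rng = np.random.default_rng(noise_ss)

    causal, strat = _indicators(config, ind_rng)
    sigma = config.sigma_matrix()
    K = config.n_variants

    families = []
    for i in range(config.n_families):
        gm, gf = simulate_parents(K, config.maf, geno_rng)
        g = transmit(gm, gf, config.n_offspring, geno_rng)
        ge = (gm + gf) / 2.0
        d = g - ge[None, :]
        y = simulate_phenotypes(
            d, ge, causal, strat, config.beta1, config.beta2, sigma, noise_rng
        )
        families.append(
            FamilyGenotypes(family_id=f"F{i + 1:04d}", gm=gm, gf=gf, g=g, y=y)
        )
    return SimulatedData(families=families, causal=causal, stratified=strat,
                         config=config)


# ---------------------------------------------------------------------------
# experiments


@dataclass
class ExperimentResult:
    """Replicated-simulation outcome: per-replicate table and rejection
    rate with an exact (Clopper-Pearson) binomial confidence interval."""

    table: pd.DataFrame
    bf_cutoff: float
    n_reps: int
    n_failed: int

    @property
    def n_ok(self) -> int:
        return int((self.table["status"] == "ok").sum())

    @property
    def n_reject(self) -> int:
        ok = self.table[self.table["status"] == "ok"]
        return int(ok["reject"].sum())

    @property
    def rejection_rate(self) -> float:
        return self.n_reject / self.n_ok if self.n_ok else float("nan")

    def confidence_interval(self, level: float = 0.95):
        k, n = self.n_reject, self.n_ok
        a = (1.0 - level) / 2.0
        lo = 0.0 if k == 0 else float(stats.beta.ppf(a, k, n - k + 1))
        hi = 1.0 if k == n else float(stats.beta.ppf(1.0 - a, k + 1, n - k))
        return lo, hi

    def summary(self) -> dict:
        lo, hi = self.confidence_interval()
        return {
            "n_reps": self.n_reps,
            "n_ok": self.n_ok,
            "n_failed": self.n_failed,
            "n_reject": self.n_reject,
            "rejection_rate": self.rejection_rate,
            "ci95_low": lo,
            "ci95_high": hi,
            "bf_cutoff": self.bf_cutoff,
            "median_bf": float(self.table.loc[self.table["status"] == "ok", "bf"].median()),
        }


def run_experiment(config: SimulationConfig, n_reps: int,
                   mcmc: MCMCConfig | None = None,
                   bf_cutoff: float = 2.0,
                   pilot: MCMCConfig | None = None,
                   ci_level: float = 0.95) -> ExperimentResult:
    """Replicate the full pipeline: simulate, estimate the null residual
    scale, fit, compute the gene Bayes factor, threshold at ``bf_cutoff``.

    A master seed (``config.seed``) spawns per-replicate sub-seed streams,
    so replicates are independent yet individually re-runnable, and runs
    sharing a master seed are coupled across configurations.  Fit failures
    are recorded in the per-replicate status, never silently dropped.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if mcmc is None:
        mcmc = MCMCConfig(iterations=5000, chains=2)
    master = np.random.SeedSequence(config.seed)
    rep_seeds = master.spawn(n_reps)

    rows = []
    n_failed = 0
    for rep, rep_ss in enumerate(rep_seeds):
        sim_ss, pilot_ss, chain_ss = rep_ss.spawn(3)
        pilot_seed = int(pilot_ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
        chain_seed = int(chain_ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
        row = {
            "rep": rep, "beta1": config.beta1, "prop_causal": config.prop_causal,
            "bf": np.nan, "reject": False, "beta1_mean": np.nan,
            "beta1_lo": np.nan, "beta1_hi": np.nan, "epsilon": np.nan,
            "status": "ok",
        }
        try:
            data = simulate_dataset(config, seed=sim_ss)
            gene = data.collapse(gene_id=f"rep{rep}")
            if not gene.informative:
                row["status"] = "skipped_no_information"
                rows.append(row)
                continue
            pilot_cfg = pilot or MCMCConfig(iterations=2000, chains=1)
            pilot_cfg = MCMCConfig(
                iterations=pilot_cfg.iterations, burn_in=pilot_cfg.burn_in,
                chains=pilot_cfg.chains, seed=pilot_seed,
                sigma2_beta=mcmc.sigma2_beta, thin=pilot_cfg.thin,
                ig_a=mcmc.ig_a, ig_b=mcmc.ig_b,
            )
            sigma_hat = estimate_sigma_eps_null(
                gene.y, None, gene.fam_index, pilot_cfg
            )
            eps = compute_epsilon(sigma_hat)
            model = FBCM(
                iterations=mcmc.iterations, burn_in=mcmc.burn_in,
                chains=mcmc.chains, thin=mcmc.thin,
                sigma2_beta=mcmc.sigma2_beta, ig_a=mcmc.ig_a, ig_b=mcmc.ig_b,
                random_state=chain_seed,
            ).fit(gene)
            res = model.bayes_factors(eps)
            lo, hi = model.credible_interval("beta1", ci_level)
            row.update(
                bf=res.gene_bf, reject=bool(res.gene_bf > bf_cutoff),
                beta1_mean=res.beta1_mean, beta1_lo=lo, beta1_hi=hi,
                epsilon=eps,
            )
        except Exception:  # noqa: BLE001 - failures are counted, not dropped
            logger.exception("replicate %d failed", rep)
            row["status"] = "failed"
            n_failed += 1
        rows.append(row)

    return ExperimentResult(
        table=pd.DataFrame(rows), bf_cutoff=bf_cutoff,
        n_reps=n_reps, n_failed=n_failed,
    )
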