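"""Hierarchical spike-indicator model and Gibbs sampler.

The phenotype of offspring j in family i is modelled as

    y_ij = mu + x_ij' c + beta1 * (alpha_r D_ij,r + alpha_s D_ij,s)
              + beta2 * (gamma_r GE_i,r + gamma_s GE_i,s) + phi_i + eps_ij

with phi_i ~ N(0, sigma2_phi), eps_ij ~ N(0, sigma2_eps), binary spike
indicators alpha_k ~ Bern(p_k), gamma_k ~ Bern(q_k), p_k, q_k ~ Beta(1, 1),
and vague N(0, sigma2_beta) priors on mu, beta1, beta2 and the covariate
coefficients c.  The pseudolocus 0 has alpha_0 = gamma_0 = 0 (Bern(0)) and
zero genotype terms, so offspring without transmission deviations reduce to
the plain mixed model.

Every full conditional is conjugate, so posterior draws come from a pure
Gibbs sweep (see ``_gibbs``).  Variance components get Inverse-Gamma(0.01,
0.01) priors, mirroring common BUGS practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy
from sklearn.base import BaseEstimator

from ._gibbs import run_gibbs_chain
from .errors import ConvergenceDiagnosticError, DimensionError, NonInformativeGeneError
from .pedigree import CollapsedGene

__all__ = [
    "MCMCConfig",
    "ModelState",
    "ChainSamples",
    "FBCM",
    "linear_predictor",
    "log_joint",
    "gibbs_step",
    "run_chain",
    "gelman_rubin",
    "estimate_sigma_eps_null",
]

_SCALAR_PARAMS = ("mu", "beta1", "beta2", "sigma2_phi", "sigma2_eps")


@dataclass
class MCMCConfig:
    """Sampler settings.

    ``sigma2_beta`` is the prior variance of the global effects (default
    1e4, a vague prior on the scale of a standardised quantitative trait).
    Burn-in defaults to the first half of the iterations.
    """

    iterations: int = 50_000
    burn_in: int | None = None
    chains: int = 3
    seed: int = 0
    sigma2_beta: float = 1e4
    thin: int = 1
    ig_a: float = 0.01
    ig_b: float = 0.01
    store_phi: bool = False

    def __post_init__(self):
        if self.burn_in is None:
            self.burn_in = self.iterations // 2
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("burn_in must satisfy 0 <= burn_in < iterations")
        if self.chains < 1:
            raise ValueError("need at least one chain")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.sigma2_beta <= 0:
            raise ValueError("sigma2_beta must be positive")

    @property
    def sigma_beta(self) -> float:
        return float(np.sqrt(self.sigma2_beta))


@dataclass
class ModelState:
    """One complete set of model parameters."""

    mu: float
    beta1: float
    beta2: float
    alpha: np.ndarray       # (K+1,) binary, alpha[0] == 0
    gamma: np.ndarray       # (K+1,) binary, gamma[0] == 0
    p: np.ndarray           # (K,) Bernoulli hyperparameters for alpha_1..K
    q: np.ndarray           # (K,)
    phi: np.ndarray         # (M,) family effects
    sigma2_phi: float
    sigma2_eps: float
    covar_coef: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=np.float64)
        self.gamma = np.asarray(self.gamma, dtype=np.float64)
        self.p = np.asarray(self.p, dtype=np.float64)
        self.q = np.asarray(self.q, dtype=np.float64)
        self.phi = np.asarray(self.phi, dtype=np.float64)
        self.covar_coef = np.asarray(self.covar_coef, dtype=np.float64)
        if self.alpha[0] != 0 or self.gamma[0] != 0:
            raise ValueError("pseudolocus indicators alpha[0], gamma[0] must be 0")
        if self.sigma2_phi <= 0 or self.sigma2_eps <= 0:
            raise ValueError("variance components must be positive")


def linear_predictor(state: ModelState, gene: CollapsedGene, covariates=None):
    """Mean of y for every offspring under ``state`` (the model's fixed +
    random structure; pseudolocus terms contribute exactly zero)."""
    if covariates is None:
        covariates = gene.covariates
    if gene.r.max(initial=0) >= state.alpha.shape[0] or gene.s.max(initial=0) >= state.alpha.shape[0]:
        raise DimensionError("collapse indices exceed indicator vector length")
    eta = np.full(gene.n_offspring, state.mu, dtype=np.float64)
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=np.float64))
        if covariates.shape[0] != gene.n_offspring:
            raise DimensionError("covariate rows do not match offspring count")
        if covariates.shape[1] != state.covar_coef.shape[0]:
            raise DimensionError("covariate columns do not match coefficient length")
        eta += covariates @ state.covar_coef
    eta += state.beta1 * (state.alpha[gene.r] * gene.d_r + state.alpha[gene.s] * gene.d_s)
    eta += state.beta2 * (state.gamma[gene.r] * gene.ge_r + state.gamma[gene.s] * gene.ge_s)
    eta += state.phi[gene.fam_index]
    return eta


def log_joint(state: ModelState, gene: CollapsedGene, y=None, covariates=None,
              config: MCMCConfig | None = None) -> float:
    """Unnormalised log posterior density of ``state`` given the gene data.

    Sum of the Gaussian likelihood, the Gaussian family-effect terms, the
    Bernoulli indicator terms, the (flat) Beta hyperpriors, the normal
    priors on the location parameters and the inverse-gamma variance
    priors.
    """
    if config is None:
        config = MCMCConfig()
    if y is None:
        y = gene.y
    y = np.asarray(y, dtype=np.float64)
    eta = linear_predictor(state, gene, covariates)
    sb = config.sigma_beta
    lp = stats.norm.logpdf(y, eta, np.sqrt(state.sigma2_eps)).sum()
    lp += stats.norm.logpdf(state.phi, 0.0, np.sqrt(state.sigma2_phi)).sum()
    a = state.alpha[1:]
    g = state.gamma[1:]
    lp += (xlogy(a, state.p) + xlogy(1.0 - a, 1.0 - state.p)).sum()
    lp += (xlogy(g, state.q) + xlogy(1.0 - g, 1.0 - state.q)).sum()
    # Beta(1,1) hyperpriors are flat on [0,1]: zero contribution
    lp += stats.norm.logpdf([state.mu, state.beta1, state.beta2], 0.0, sb).sum()
    lp += stats.norm.logpdf(state.covar_coef, 0.0, sb).sum()
    lp += stats.invgamma.logpdf(state.sigma2_phi, config.ig_a, scale=config.ig_b)
    lp += stats.invgamma.logpdf(state.sigma2_eps, config.ig_a, scale=config.ig_b)
    return float(lp)


# ---------------------------------------------------------------------------
# chain output


@dataclass
class ChainSamples:
    """Post-burn-in draws across chains.

    ``draws[name]`` has shape (chains, kept) for scalars and
    (chains, kept, dim) for vector parameters.
    """

    draws: dict

    @property
    def n_chains(self) -> int:
        return self.draws["beta1"].shape[0]

    @property
    def n_kept(self) -> int:
        return self.draws["beta1"].shape[1]

    @property
    def n_draws(self) -> int:
        return self.n_chains * self.n_kept

    def pooled(self, name: str) -> np.ndarray:
        a = self.draws[name]
        return a.reshape(-1, *a.shape[2:])

    def rhat(self) -> dict:
        """Gelman-Rubin potential scale reduction per continuous scalar
        parameter (and per covariate coefficient)."""
        out = {}
        for name in _SCALAR_PARAMS:
            out[name] = gelman_rubin(self.draws[name])
        coef = self.draws.get("covar_coef")
        if coef is not None and coef.shape[2]:
            for pidx in range(coef.shape[2]):
                out[f"covar_coef_{pidx + 1}"] = gelman_rubin(coef[:, :, pidx])
        return out

    def rhat_max(self) -> float:
        return max(self.rhat().values())

    def autocorr(self, name: str, nlags: int = 20) -> np.ndarray:
        """Mean within-chain autocorrelation at lags 1..nlags."""
        a = self.draws[name]
        if a.ndim != 2:
            raise ValueError("autocorrelation summary is defined for scalar parameters")
        nlags = min(nlags, self.n_kept - 1)
        acfs = np.zeros(nlags)
        for c in range(self.n_chains):
            x = a[c] - a[c].mean()
            denom = (x * x).sum()
            if denom == 0:
                continue
            for lag in range(1, nlags + 1):
                acfs[lag - 1] += (x[:-lag] * x[lag:]).sum() / denom
        return acfs / self.n_chains

    def to_frame(self) -> pd.DataFrame:
        """Flat table: one row per kept draw with a chain id column."""
        cols = {"chain": np.repeat(np.arange(self.n_chains), self.n_kept)}
        for name, a in self.draws.items():
            if a.ndim == 2:
                cols[name] = a.reshape(-1)
            else:
                for d in range(a.shape[2]):
                    cols[f"{name}_{d + 1}"] = a[:, :, d].reshape(-1)
        return pd.DataFrame(cols)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def gelman_rubin(draws) -> float:
    """Potential scale reduction factor for one parameter.

    ``draws`` is (chains, length).  R-hat = sqrt(((n-1)/n W + B/n) / W)
    with W the mean within-chain variance and B/n the variance of the
    chain means.
    """
    x = np.asarray(draws, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ConvergenceDiagnosticError("R-hat requires at least two chains")
    if x.shape[1] < 10:
        raise ConvergenceDiagnosticError("R-hat requires chain length >= 10")
    n = x.shape[1]
    w = x.var(axis=1, ddof=1).mean()
    b_over_n = x.mean(axis=1).var(ddof=1)
    if w == 0:
        return 1.0 if b_over_n == 0 else float("inf")
    var_plus = (n - 1) / n * w + b_over_n
    return float(np.sqrt(var_plus / w))


# ---------------------------------------------------------------------------
# running the sampler


def _pack_gene(gene: CollapsedGene, covariates):
    N = gene.n_offspring
    K = gene.n_variants
    r = np.ascontiguousarray(gene.r, dtype=np.int64)
    s = np.ascontiguousarray(gene.s, dtype=np.int64)
    dr = np.ascontiguousarray(gene.d_r, dtype=np.float64)
    ds = np.ascontiguousarray(gene.d_s, dtype=np.float64)
    ger = np.ascontiguousarray(gene.ge_r, dtype=np.float64)
    ges = np.ascontiguousarray(gene.ge_s, dtype=np.float64)
    fam = np.ascontiguousarray(gene.fam_index, dtype=np.int64)
    M = gene.n_families
    fam_sizes = np.bincount(fam, minlength=M).astype(np.float64)

    idx_lists = [[] for _ in range(K + 1)]
    d_lists = [[] for _ in range(K + 1)]
    ge_lists = [[] for _ in range(K + 1)]
    for j in range(N):
        if r[j] > 0:
            idx_lists[r[j]].append(j)
            d_lists[r[j]].append(dr[j])
            ge_lists[r[j]].append(ger[j])
        if s[j] > 0:
            idx_lists[s[j]].append(j)
            d_lists[s[j]].append(ds[j])
            ge_lists[s[j]].append(ges[j])
    loc_off = np.zeros(K + 1, dtype=np.int64)
    for k in range(1, K + 1):
        loc_off[k] = loc_off[k - 1] + len(idx_lists[k])
    loc_idx = np.array(
        [j for k in range(1, K + 1) for j in idx_lists[k]], dtype=np.int64
    )
    loc_d = np.array(
        [v for k in range(1, K + 1) for v in d_lists[k]], dtype=np.float64
    )
    loc_ge = np.array(
        [v for k in range(1, K + 1) for v in ge_lists[k]], dtype=np.float64
    )

    if covariates is None:
        X = np.zeros((N, 0))
    else:
        X = np.ascontiguousarray(np.atleast_2d(covariates), dtype=np.float64)
        if X.shape[0] != N:
            raise DimensionError("covariate rows do not match offspring count")
    return dict(
        X=X, fam=fam, fam_sizes=fam_sizes, dr=dr, ds=ds, ger=ger, ges=ges,
        r=r, s=s, loc_off=loc_off, loc_idx=loc_idx, loc_d=loc_d,
        loc_ge=loc_ge, K=K, M=M, N=N,
    )


def _fixed_value(fixed, key, default):
    if fixed is not None and key in fixed:
        return fixed[key], False
    return default, True


def _indicator_init(fixed, key, K):
    if fixed is not None and key in fixed:
        v = np.asarray(fixed[key], dtype=np.float64)
        if v.shape[0] == K:
            v = np.concatenate([[0.0], v])
        elif v.shape[0] != K + 1:
            raise DimensionError(f"fixed {key} must have length K or K+1")
        if v[0] != 0:
            raise ValueError(f"{key}[0] (pseudolocus) must stay 0")
        return v, False
    return np.zeros(K + 1), True


def run_chain(gene: CollapsedGene, y=None, covariates=None,
              config: MCMCConfig | None = None, fixed: dict | None = None,
              require_informative: bool = True) -> ChainSamples:
    """Run ``config.chains`` independent Gibbs chains from dispersed starts.

    ``fixed`` clamps parameters at given values instead of sampling them
    (keys: mu, beta1, beta2, coef, phi, alpha, gamma, sigma2_phi,
    sigma2_eps); used for pilot null fits and for conjugate validation.
    Fully reproducible given ``config.seed``.
    """
    if config is None:
        config = MCMCConfig()
    if y is None:
        y = gene.y
    y = np.ascontiguousarray(y, dtype=np.float64)
    if covariates is None:
        covariates = gene.covariates
    if require_informative and not gene.informative:
        raise NonInformativeGeneError(
            f"gene {gene.gene_id}: no offspring shows a transmission deviation"
        )

    pack = _pack_gene(gene, covariates)
    K, M, N, P = pack["K"], pack["M"], pack["N"], pack["X"].shape[1]

    b1_fix, upd_b1 = _fixed_value(fixed, "beta1", None)
    b2_fix, upd_b2 = _fixed_value(fixed, "beta2", None)
    mu_fix, upd_mu = _fixed_value(fixed, "mu", None)
    coef_fix, upd_coef = _fixed_value(fixed, "coef", None)
    phi_fix, upd_phi = _fixed_value(fixed, "phi", None)
    s2phi_fix, upd_s2phi = _fixed_value(fixed, "sigma2_phi", None)
    s2eps_fix, upd_s2eps = _fixed_value(fixed, "sigma2_eps", None)
    alpha0, upd_alpha = _indicator_init(fixed, "alpha", K)
    gamma0, upd_gamma = _indicator_init(fixed, "gamma", K)

    var0 = float(np.var(y)) if N >= 2 and np.var(y) > 0 else 1.0
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.chains)

    per_chain = []
    for c, child in enumerate(children):
        init_rng = np.random.default_rng(child)
        kernel_seed = int(child.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
        scale = 1.0 + c
        mu0 = mu_fix if not upd_mu else float(init_rng.normal()) * scale
        b10 = b1_fix if not upd_b1 else float(init_rng.normal()) * scale
        b20 = b2_fix if not upd_b2 else float(init_rng.normal()) * scale
        coef0 = (np.full(P, float(coef_fix)) if np.isscalar(coef_fix)
                 else np.asarray(coef_fix, dtype=np.float64)) if not upd_coef \
            else np.zeros(P)
        phi0 = (np.full(M, float(phi_fix)) if np.isscalar(phi_fix)
                else np.asarray(phi_fix, dtype=np.float64)) if not upd_phi \
            else np.zeros(M)
        s2phi0 = float(s2phi_fix) if not upd_s2phi else var0
        s2eps0 = float(s2eps_fix) if not upd_s2eps else var0

        out = run_gibbs_chain(
            y, pack["X"], pack["fam"], pack["fam_sizes"],
            pack["dr"], pack["ds"], pack["ger"], pack["ges"],
            pack["r"], pack["s"],
            pack["loc_off"], pack["loc_idx"], pack["loc_d"], pack["loc_ge"], K,
            config.iterations, config.burn_in, config.thin, config.store_phi,
            float(mu0), float(b10), float(b20), coef0, phi0, alpha0, gamma0,
            s2phi0, s2eps0,
            config.sigma2_beta, config.ig_a, config.ig_b,
            upd_mu, upd_b1, upd_b2, upd_coef, upd_alpha, upd_gamma,
            upd_phi, upd_s2phi, upd_s2eps,
            kernel_seed,
        )
        per_chain.append(out)

    names = ("mu", "beta1", "beta2", "covar_coef", "alpha", "gamma",
             "p", "q", "sigma2_phi", "sigma2_eps", "phi")
    draws = {}
    for idx, name in enumerate(names):
        if name == "phi" and not config.store_phi:
            continue
        draws[name] = np.stack([chain[idx] for chain in per_chain])
    return ChainSamples(draws)


def gibbs_step(state: ModelState, gene: CollapsedGene, y=None, covariates=None,
               config: MCMCConfig | None = None, seed: int = 0) -> ModelState:
    """One full Gibbs sweep from ``state``; returns the new state.

    Provided for inspection and validation; bulk sampling should use
    :func:`run_chain`, which keeps the whole loop inside compiled code.
    """
    if config is None:
        config = MCMCConfig()
    if y is None:
        y = gene.y
    y = np.ascontiguousarray(y, dtype=np.float64)
    if covariates is None:
        covariates = gene.covariates
    pack = _pack_gene(gene, covariates)
    out = run_gibbs_chain(
        y, pack["X"], pack["fam"], pack["fam_sizes"],
        pack["dr"], pack["ds"], pack["ger"], pack["ges"],
        pack["r"], pack["s"],
        pack["loc_off"], pack["loc_idx"], pack["loc_d"], pack["loc_ge"],
        pack["K"],
        1, 0, 1, True,
        float(state.mu), float(state.beta1), float(state.beta2),
        np.asarray(state.covar_coef, dtype=np.float64),
        np.asarray(state.phi, dtype=np.float64),
        np.asarray(state.alpha, dtype=np.float64),
        np.asarray(state.gamma, dtype=np.float64),
        float(state.sigma2_phi), float(state.sigma2_eps),
        config.sigma2_beta, config.ig_a, config.ig_b,
        True, True, True, True, True, True, True, True, True,
        int(seed),
    )
    (mu_s, b1_s, b2_s, coef_s, alpha_s, gamma_s, p_s, q_s,
     s2phi_s, s2eps_s, phi_s) = out
    K = pack["K"]
    alpha = np.concatenate([[0.0], alpha_s[0].astype(np.float64)])
    gamma = np.concatenate([[0.0], gamma_s[0].astype(np.float64)])
    return ModelState(
        mu=float(mu_s[0]), beta1=float(b1_s[0]), beta2=float(b2_s[0]),
        alpha=alpha, gamma=gamma, p=p_s[0].copy(), q=q_s[0].copy(),
        phi=phi_s[0].copy(), sigma2_phi=float(s2phi_s[0]),
        sigma2_eps=float(s2eps_s[0]), covar_coef=coef_s[0].copy(),
    )


def estimate_sigma_eps_null(y, covariates=None, fam_index=None,
                            config: MCMCConfig | None = None) -> float:
    """Posterior-mean residual standard deviation under the no-genotype
    model (intercept + covariates + family effect only).

    Used to set the practical-significance threshold epsilon = 0.2 *
    sigma_eps_hat of the composite hypothesis.
    """
    y = np.asarray(y, dtype=np.float64)
    if fam_index is None:
        fam_index = np.arange(y.shape[0])
    fam_index = np.asarray(fam_index, dtype=np.int64)
    if len(np.unique(fam_index)) < 2:
        raise ValueError("need at least two families to separate variance components")
    if np.ptp(y) == 0:
        warnings.warn("constant phenotype: residual variance estimate is degenerate")
    M = int(fam_index.max()) + 1
    N = y.shape[0]
    gene = CollapsedGene(
        gene_id="__null__",
        mafs=np.zeros(0),
        ge=np.zeros((M, 1)),
        d=np.zeros((N, 1)),
        fam_index=fam_index,
        r=np.zeros(N, dtype=np.int64),
        s=np.zeros(N, dtype=np.int64),
        y=y,
        covariates=None if covariates is None else np.atleast_2d(covariates),
    )
    if config is None:
        config = MCMCConfig(iterations=2000, chains=1)
    samples = run_chain(
        gene, y, covariates, config,
        fixed={"beta1": 0.0, "beta2": 0.0, "alpha": np.zeros(0), "gamma": np.zeros(0)},
        require_informative=False,
    )
    return float(np.sqrt(samples.pooled("sigma2_eps")).mean())


# ---------------------------------------------------------------------------
# estimator


class FBCM(BaseEstimator):
    """Family-based Bayesian collapsing model.

    A scikit-learn style estimator: ``fit`` takes a
    :class:`~fbcm.pedigree.CollapsedGene` (and optionally ``y`` /
    ``covariates`` overriding those stored on the gene) and draws from the
    joint posterior with a conjugate Gibbs sampler.  Fitted attributes
    expose the pooled chains, convergence diagnostics and posterior
    summaries; :meth:`bayes_factors` computes the gene-level hybrid Bayes
    factor and per-variant marginal Bayes factors.

    Parameters
    ----------
    iterations, burn_in, chains, thin : sampler schedule; burn-in defaults
        to half the iterations.
    sigma2_beta : prior variance of mu, beta1, beta2 and covariate
        coefficients (default 1e4).
    ig_a, ig_b : Inverse-Gamma hyperparameters of both variance components.
    random_state : master seed; chains get dispersed initial values and
        independent sub-seeds.
    """

    def __init__(self, iterations=50_000, burn_in=None, chains=3, thin=1,
                 sigma2_beta=1e4, ig_a=0.01, ig_b=0.01, store_phi=False,
                 random_state=0):
        self.iterations = iterations
        self.burn_in = burn_in
        self.chains = chains
        self.thin = thin
        self.sigma2_beta = sigma2_beta
        self.ig_a = ig_a
        self.ig_b = ig_b
        self.store_phi = store_phi
        self.random_state = random_state

    def _config(self) -> MCMCConfig:
        return MCMCConfig(
            iterations=self.iterations, burn_in=self.burn_in,
            chains=self.chains, seed=self.random_state if self.random_state is not None else 0,
            sigma2_beta=self.sigma2_beta, thin=self.thin,
            ig_a=self.ig_a, ig_b=self.ig_b, store_phi=self.store_phi,
        )

    def fit(self, X: CollapsedGene, y=None, covariates=None, fixed=None):
        config = self._config()
        self.samples_ = run_chain(X, y, covariates, config, fixed=fixed)
        self.n_variants_ = X.n_variants
        self.rhat_ = self.samples_.rhat() if config.chains >= 2 else {}
        self.rhat_max_ = max(self.rhat_.values()) if self.rhat_ else float("nan")
        self.beta1_mean_ = float(self.samples_.pooled("beta1").mean())
        self.beta2_mean_ = float(self.samples_.pooled("beta2").mean())
        self.mu_mean_ = float(self.samples_.pooled("mu").mean())
        self.sigma_eps_mean_ = float(np.sqrt(self.samples_.pooled("sigma2_eps")).mean())
        self.sigma_phi_mean_ = float(np.sqrt(self.samples_.pooled("sigma2_phi")).mean())
        self.alpha_mean_ = self.samples_.pooled("alpha").mean(axis=0)
        self.n_draws_ = self.samples_.n_draws
        return self

    def credible_interval(self, name: str = "beta1", level: float = 0.95):
        """Equal-tailed posterior credible interval for a scalar parameter."""
        draws = self.samples_.pooled(name)
        lo = (1.0 - level) / 2.0
        return tuple(np.quantile(draws, [lo, 1.0 - lo]))

    def bayes_factors(self, epsilon: float, joint: bool = True):
        """Hybrid gene-level and marginal variant-level Bayes factors.

        ``epsilon`` is the practical-significance threshold (0.2 x the
        null residual standard deviation; see
        :func:`estimate_sigma_eps_null`).
        """
        from .bayes import gene_bf

        return gene_bf(self.samples_, epsilon,
                       float(np.sqrt(self.sigma2_beta)), joint=joint)
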