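"""Sampler, model density, diagnostics and the null variance pilot."""

import numpy as np
import pytest
from scipy import stats

from fbcm.errors import ConvergenceDiagnosticError, NonInformativeGeneError
from fbcm.model import (
    FBCM,
    MCMCConfig,
    ModelState,
    estimate_sigma_eps_null,
    gelman_rubin,
    gibbs_step,
    linear_predictor,
    log_joint,
    run_chain,
)
from fbcm.pedigree import CollapsedGene

from conftest import make_gene


def random_state(rng, K, M, P=0):
    alpha = np.concatenate([[0.0], rng.integers(0, 2, K)]).astype(float)
    gamma = np.concatenate([[0.0], rng.integers(0, 2, K)]).astype(float)
    return ModelState(
        mu=rng.normal(), beta1=rng.normal(), beta2=rng.normal(),
        alpha=alpha, gamma=gamma,
        p=rng.uniform(0.05, 0.95, K), q=rng.uniform(0.05, 0.95, K),
        phi=rng.normal(0, 1, M),
        sigma2_phi=rng.uniform(0.5, 2), sigma2_eps=rng.uniform(0.5, 2),
        covar_coef=rng.normal(0, 1, P),
    )


# ---------------------------------------------------------------------------
# linear predictor and joint density


def test_linear_predictor_zero_state():
    gene = make_gene([[0.5, 0.0], [0.0, -0.5]], [0.002, 0.004], [1.0, 2.0])
    state = random_state(np.random.default_rng(0), 2, 2)
    state.mu = 0.0
    state.phi[:] = 0.0
    state.alpha[1:] = 0.0
    state.gamma[1:] = 0.0
    np.testing.assert_allclose(linear_predictor(state, gene), 0.0)


def test_linear_predictor_pseudolocus_inert():
    # an offspring with r = s = 0 gets mu + phi regardless of beta1/beta2
    gene = make_gene([[0.0, 0.0]], [0.002, 0.004], [1.0])
    state = random_state(np.random.default_rng(1), 2, 1)
    eta = linear_predictor(state, gene)
    np.testing.assert_allclose(eta, state.mu + state.phi[0])


def test_linear_predictor_single_term():
    gene = make_gene([[0.0, 0.5]], [0.002, 0.004], [1.0])
    state = random_state(np.random.default_rng(2), 2, 1)
    state.mu = 0.0
    state.phi[:] = 0.0
    state.beta1 = 1.5
    state.beta2 = 0.0
    state.alpha[1:] = [0.0, 1.0]
    # deviation 0.5 at locus 2 with alpha_2 = 1 -> beta1 * 0.5
    assert linear_predictor(state, gene)[0] == pytest.approx(0.75)


def test_log_joint_decreases_with_residual():
    gene = make_gene([[0.5], [-0.5]], [0.002], [0.0, 0.0])
    state = random_state(np.random.default_rng(3), 1, 2)
    eta = linear_predictor(state, gene)
    base = log_joint(state, gene, y=eta)
    worse = log_joint(state, gene, y=eta + 1.0)
    worst = log_joint(state, gene, y=eta + 2.0)
    assert base > worse > worst


def test_log_joint_matches_term_by_term_oracle():
    rng = np.random.default_rng(11)
    cfg = MCMCConfig(iterations=100, sigma2_beta=25.0, ig_a=0.5, ig_b=0.5)
    gene = make_gene(
        rng.choice([-0.5, 0.0, 0.5], size=(6, 3)),
        [0.002, 0.004, 0.006],
        rng.normal(size=6),
        fam_index=[0, 0, 1, 1, 2, 2],
        ge_body=rng.choice([0.0, 0.5, 1.0], size=(3, 3)),
        covariates=rng.normal(size=(6, 2)),
    )
    for _ in range(100):
        st_ = random_state(rng, 3, 3, P=2)
        # independent summation oracle
        a, g = st_.alpha, st_.gamma
        eta = (st_.mu + gene.covariates @ st_.covar_coef
               + st_.beta1 * (a[gene.r] * gene.d_r + a[gene.s] * gene.d_s)
               + st_.beta2 * (g[gene.r] * gene.ge_r + g[gene.s] * gene.ge_s)
               + st_.phi[gene.fam_index])
        want = 0.0
        for j in range(6):
            want += stats.norm.logpdf(gene.y[j], eta[j], np.sqrt(st_.sigma2_eps))
        for i in range(3):
            want += stats.norm.logpdf(st_.phi[i], 0, np.sqrt(st_.sigma2_phi))
        for k in range(3):
            want += np.log(st_.p[k] if a[k + 1] else 1 - st_.p[k])
            want += np.log(st_.q[k] if g[k + 1] else 1 - st_.q[k])
        for v in (st_.mu, st_.beta1, st_.beta2, *st_.covar_coef):
            want += stats.norm.logpdf(v, 0, 5.0)
        for s2 in (st_.sigma2_phi, st_.sigma2_eps):
            want += stats.invgamma.logpdf(s2, 0.5, scale=0.5)
        assert log_joint(st_, gene, config=cfg) == pytest.approx(want, abs=1e-8)


def test_model_state_rejects_bad_values():
    with pytest.raises(ValueError):
        ModelState(0, 0, 0, [1.0, 0.0], [0.0, 0.0], [0.5], [0.5], [0.0], 1.0, 1.0)
    with pytest.raises(ValueError):
        ModelState(0, 0, 0, [0.0, 0.0], [0.0, 0.0], [0.5], [0.5], [0.0], 1.0, -1.0)


def test_pseudolocus_column_must_be_zero():
    with pytest.raises(ValueError):
        CollapsedGene("bad", np.array([0.005]), np.ones((1, 2)), np.zeros((1, 2)),
                      np.zeros(1, dtype=int), np.zeros(1, dtype=int),
                      np.zeros(1, dtype=int), y=np.zeros(1))


# ---------------------------------------------------------------------------
# Gelman-Rubin


def test_gelman_rubin_identical_chains():
    x = np.sin(np.arange(200.0))
    exact = np.sqrt((200 - 1) / 200)  # zero between-chain variance
    assert gelman_rubin(np.stack([x, x])) == pytest.approx(exact, abs=1e-6)


def test_gelman_rubin_separated_chains(rng):
    chains = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
    assert gelman_rubin(chains) > 2


def test_gelman_rubin_matches_textbook_formula(rng):
    for _ in range(20):
        x = rng.normal(size=(rng.integers(2, 5), rng.integers(10, 60)))
        m, n = x.shape
        w = np.mean([np.var(x[c], ddof=1) for c in range(m)])
        b = n * np.var(x.mean(axis=1), ddof=1)
        want = np.sqrt(((n - 1) / n * w + b / n) / w)
        assert gelman_rubin(x) == pytest.approx(want, abs=1e-10)


def test_gelman_rubin_undefined_cases():
    with pytest.raises(ConvergenceDiagnosticError):
        gelman_rubin(np.zeros((1, 100)))
    with pytest.raises(ConvergenceDiagnosticError):
        gelman_rubin(np.zeros((2, 5)))


# ---------------------------------------------------------------------------
# sampler behaviour


def test_chain_determinism(informative_gene):
    cfg = MCMCConfig(iterations=600, chains=2, seed=5)
    a = run_chain(informative_gene, config=cfg)
    b = run_chain(informative_gene, config=cfg)
    for name in a.draws:
        np.testing.assert_array_equal(a.draws[name], b.draws[name])


def test_hyperparameter_full_conditional(informative_gene):
    # p_k | alpha_k=1 ~ Beta(2,1) (mean 2/3); | alpha_k=0 ~ Beta(1,2) (mean 1/3)
    K = informative_gene.n_variants
    cfg = MCMCConfig(iterations=4000, chains=1, seed=8)
    up = run_chain(informative_gene, config=cfg, fixed={"alpha": np.ones(K)})
    down = run_chain(informative_gene, config=cfg, fixed={"alpha": np.zeros(K)})
    assert up.pooled("p").mean() == pytest.approx(2 / 3, abs=0.02)
    assert down.pooled("p").mean() == pytest.approx(1 / 3, abs=0.02)


def test_beta1_conjugate_posterior_with_clamped_indicators(informative_gene):
    # with indicators, variances, phi and mu all clamped, every beta1 draw is
    # an exact draw from the one-predictor Gaussian regression posterior
    gene = informative_gene
    K = gene.n_variants
    s2e, s2b = 1.3, 1e4
    cfg = MCMCConfig(iterations=4000, burn_in=0, chains=2, seed=13,
                     sigma2_beta=s2b)
    samples = run_chain(gene, config=cfg, fixed={
        "alpha": np.ones(K), "gamma": np.zeros(K), "mu": 0.0, "phi": 0.0,
        "sigma2_eps": s2e, "sigma2_phi": 1.0, "beta2": 0.0,
    })
    x = gene.d_r + gene.d_s
    prec = x @ x / s2e + 1.0 / s2b
    mean = (x @ gene.y / s2e) / prec
    sd = 1.0 / np.sqrt(prec)
    draws = samples.pooled("beta1")
    mcse = sd / np.sqrt(draws.size)
    assert abs(draws.mean() - mean) < 3 * mcse
    assert draws.std() == pytest.approx(sd, rel=0.1)


def test_prior_recovery_without_data():
    # zero offspring: beta1 marginal is N(0, sigma_beta^2), alpha_k ~ Bern(1/2)
    gene = CollapsedGene("empty", np.full(5, 0.005), np.zeros((0, 6)),
                         np.zeros((0, 6)), np.zeros(0, dtype=int),
                         np.zeros(0, dtype=int), np.zeros(0, dtype=int),
                         y=np.zeros(0))
    cfg = MCMCConfig(iterations=20_000, burn_in=0, chains=1, seed=21,
                     sigma2_beta=1e4)
    samples = run_chain(gene, config=cfg, require_informative=False)
    b1 = samples.pooled("beta1")
    ks = stats.kstest(b1, stats.norm(0, 100).cdf)
    assert ks.pvalue > 0.01
    a = samples.pooled("alpha").mean(axis=0)
    # the (alpha_k, p_k) chain is a two-state Markov chain with lag-1
    # autocorrelation 1/3, so Var(mean) = 0.25/n * (1+1/3)/(1-1/3)
    se = np.sqrt(0.25 / b1.size * 2.0)
    assert np.all(np.abs(a - 0.5) < 4 * se)


def test_rhat_small_on_well_specified_gene(informative_gene):
    cfg = MCMCConfig(iterations=3000, chains=3, seed=2)
    samples = run_chain(informative_gene, config=cfg)
    assert samples.rhat_max() < 1.1


def test_noninformative_gene_raises_skip_signal():
    gene = make_gene(np.zeros((4, 2)), [0.002, 0.004], np.zeros(4))
    with pytest.raises(NonInformativeGeneError):
        run_chain(gene, config=MCMCConfig(iterations=100, chains=1))


def test_gibbs_step_produces_valid_state(informative_gene):
    rng = np.random.default_rng(31)
    state = random_state(rng, informative_gene.n_variants,
                         informative_gene.n_families)
    new = gibbs_step(state, informative_gene, seed=3)
    assert new.sigma2_eps > 0 and new.sigma2_phi > 0
    assert new.alpha[0] == 0 and new.gamma[0] == 0
    assert set(np.unique(new.alpha)) <= {0.0, 1.0}
    assert new.beta1 != state.beta1  # continuous update moved


def test_fbcm_estimator_interface(informative_gene):
    model = FBCM(iterations=800, chains=2, random_state=4)
    params = model.get_params()
    assert params["iterations"] == 800
    model.set_params(iterations=1000)
    fitted = model.fit(informative_gene)
    assert fitted is model
    assert model.samples_.n_draws == 2 * 500
    assert np.isfinite(model.beta1_mean_)
    lo, hi = model.credible_interval("beta1")
    assert lo < model.beta1_mean_ < hi
    frame = model.samples_.to_frame()
    assert {"chain", "beta1", "sigma2_eps"} <= set(frame.columns)


# ---------------------------------------------------------------------------
# null variance pilot


def test_sigma_eps_null_variance_decomposition():
    # exchangeable sibling covariance [[2,1],[1,2]] splits into
    # sigma2_phi = 1 (shared) and sigma2_eps = 1 (individual)
    rng = np.random.default_rng(17)
    M = 300
    L = np.linalg.cholesky([[2.0, 1.0], [1.0, 2.0]])
    y = (rng.standard_normal((M, 2)) @ L.T).ravel()
    fam = np.repeat(np.arange(M), 2)
    cfg = MCMCConfig(iterations=3000, chains=1, seed=6)
    est = estimate_sigma_eps_null(y, None, fam, cfg)
    assert est == pytest.approx(1.0, rel=0.15)
    # location invariance and scale equivariance (within MC error)
    est_shift = estimate_sigma_eps_null(y + 7.0, None, fam, cfg)
    est_scale = estimate_sigma_eps_null(2.0 * y, None, fam, cfg)
    assert est_shift == pytest.approx(est, rel=0.02)
    assert est_scale == pytest.approx(2.0 * est, rel=0.05)


def test_sigma_eps_null_needs_multiple_families():
    with pytest.raises(ValueError):
        estimate_sigma_eps_null(np.zeros(4), None, np.zeros(4, dtype=int))
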