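import numpy as np
import pytest
from hypothesis import settings

from fbcm.model import ChainSamples
from fbcm.pedigree import CollapsedGene

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=100)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def make_gene(d_body, mafs, y, fam_index=None, ge_body=None, covariates=None,
              gene_id="g"):
    """Assemble a CollapsedGene from a deviation matrix without the
    pseudolocus column; (r, s) are derived by MAF rank."""
    d_body = np.atleast_2d(np.asarray(d_body, dtype=np.float64))
    N, K = d_body.shape
    mafs = np.asarray(mafs, dtype=np.float64)
    if fam_index is None:
        fam_index = np.arange(N)
    fam_index = np.asarray(fam_index, dtype=np.int64)
    M = int(fam_index.max()) + 1 if N else 0
    if ge_body is None:
        ge_body = np.zeros((M, K))
    ge = np.hstack([np.zeros((M, 1)), np.atleast_2d(ge_body)]) if M else np.zeros((0, K + 1))
    d = np.hstack([np.zeros((N, 1)), d_body])
    order = np.argsort(mafs, kind="stable")
    rank = np.empty(K, dtype=int)
    rank[order] = np.arange(K)
    r = np.zeros(N, dtype=np.int64)
    s = np.zeros(N, dtype=np.int64)
    for j in range(N):
        nz = np.flatnonzero(d_body[j] != 0)
        nz = nz[np.argsort(rank[nz])]
        if nz.size:
            r[j] = nz[0] + 1
        if nz.size > 1:
            s[j] = nz[1] + 1
    return CollapsedGene(gene_id, mafs, ge, d, fam_index, r, s,
                         y=np.asarray(y, dtype=np.float64), covariates=covariates)


def make_samples(beta1, alpha, **extra):
    """ChainSamples with one chain holding the given beta1 / alpha draws."""
    beta1 = np.asarray(beta1, dtype=np.float64)
    alpha = np.atleast_2d(np.asarray(alpha))
    draws = {"beta1": beta1[None, :], "alpha": alpha[None, :, :]}
    for name, val in extra.items():
        val = np.asarray(val, dtype=np.float64)
        draws[name] = val[None, ...]
    return ChainSamples(draws)


@pytest.fixture
def informative_gene(rng):
    """A small, clearly informative gene: 40 families x 2 sibs, 4 loci."""
    from fbcm.pedigree import FamilyGenotypes, collapse_gene
    from fbcm.simulate import simulate_parents, transmit

    mafs = np.array([0.002, 0.004, 0.006, 0.008])
    fams = []
    for i in range(40):
        gm, gf = simulate_parents(4, 0.2, rng)
        g = transmit(gm, gf, 2, rng)
        d = g - (gm + gf)[None, :] / 2.0
        y = 1.0 * d.sum(axis=1) + rng.normal(0, 1, 2)
        fams.append(FamilyGenotypes(f"f{i}", gm, gf, g, y))
    return collapse_gene(fams, mafs, gene_id="toy")
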