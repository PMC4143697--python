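"""Decomposition, collapsing indices, MAF estimation and filtering."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fbcm.errors import DimensionError, InvalidGenotypeError, MissingDataError
from fbcm.pedigree import (
    FamilyGenotypes,
    collapse_gene,
    collapse_indices,
    deviation,
    estimate_maf,
    expected_score,
    filter_rare,
    mendelian_valid,
    multi_carrier_probability,
)
from fbcm.simulate import SimulationConfig, simulate_dataset, simulate_parents, transmit


@pytest.mark.parametrize(
    "gm, gf, expected",
    [(1, 0, 0.5), (0, 0, 0.0), (2, 2, 2.0), (1, 1, 1.0), (2, 0, 1.0)],
)
def test_expected_score(gm, gf, expected):
    assert expected_score(gm, gf) == expected


def test_expected_score_rejects_invalid_genotype():
    with pytest.raises(InvalidGenotypeError):
        expected_score(3, 0)
    with pytest.raises(InvalidGenotypeError):
        expected_score(np.array([0, 1]), np.array([0, -1]))


def test_deviation_direct_subtraction():
    assert deviation(1, 0.5) == 0.5
    assert deviation(0, 0.0) == 0.0
    np.testing.assert_allclose(deviation([0, 1, 2], [0.5, 0.5, 1.5]),
                               [-0.5, 0.5, 0.5])


def test_deviation_het_by_ref_parents_two_outcomes():
    # parents 1 x 0: offspring can only be 0 or 1, so D is -0.5 or +0.5
    ge = expected_score(1, 0)
    outcomes = {float(deviation(g, ge)) for g in (0, 1)}
    assert outcomes == {-0.5, 0.5}
    assert not mendelian_valid(1, 0, 2)


def test_deviation_bounded_and_centered_under_transmission(rng):
    # over many random transmissions D stays in [-1, 1] with mean ~ 0
    n = 20_000
    gm, gf = rng.integers(0, 3, n), rng.integers(0, 3, n)
    g = np.array([transmit(np.array([a]), np.array([b]), 1, rng)[0, 0]
                  for a, b in zip(gm[:500], gf[:500])])
    d_small = deviation(g, expected_score(gm[:500], gf[:500]))
    assert d_small.min() >= -1 and d_small.max() <= 1
    # large-sample mean check at a single informative configuration
    g_het = transmit(np.array([1]), np.array([1]), n, rng)[:, 0]
    d = deviation(g_het, np.full(n, 1.0))
    se = d.std(ddof=1) / np.sqrt(n)
    assert abs(d.mean()) < 3 * se


@pytest.mark.parametrize(
    "d_row, mafs, expected",
    [
        ([0, 0, 0], [0.001, 0.002, 0.003], (0, 0)),
        ([0, 0, 0.5], [0.001, 0.002, 0.003], (3, 0)),
        ([0.5, -0.5, 1.0], [0.009, 0.002, 0.004], (2, 3)),
    ],
)
def test_collapse_indices_examples(d_row, mafs, expected):
    assert collapse_indices(d_row, mafs) == expected


def test_collapse_indices_dimension_mismatch():
    with pytest.raises(DimensionError):
        collapse_indices([0.5, 0.5], [0.001])


def test_collapse_indices_tie_break_by_position():
    # equal MAFs: smaller genomic position wins
    r, s = collapse_indices([0.5, 0.5], [0.005, 0.005], positions=[200, 100])
    assert (r, s) == (2, 1)


def test_collapse_indices_matches_bruteforce_oracle():
    rng = np.random.default_rng(7)
    for _ in range(1000):
        K = rng.integers(1, 9)
        d_row = rng.choice([-1.0, -0.5, 0.0, 0.0, 0.5, 1.0], size=K)
        mafs = rng.choice([0.001, 0.002, 0.005, 0.009], size=K)
        pos = rng.permutation(K) * 10
        # oracle: sort deviating loci by (maf, position), take first two
        deviating = sorted(
            (int(k) for k in np.flatnonzero(d_row != 0)),
            key=lambda k: (mafs[k], pos[k]),
        )
        want = (
            deviating[0] + 1 if deviating else 0,
            deviating[1] + 1 if len(deviating) > 1 else 0,
        )
        assert collapse_indices(d_row, mafs, positions=pos) == want


@given(st.lists(st.sampled_from([-1.0, -0.5, 0.0, 0.5, 1.0]), min_size=1, max_size=8))
def test_collapse_indices_structural_invariants(d_row):
    mafs = np.linspace(0.001, 0.009, len(d_row))
    r, s = collapse_indices(d_row, mafs)
    if r == 0:
        assert s == 0
    else:
        assert d_row[r - 1] != 0
    if s != 0:
        assert mafs[r - 1] <= mafs[s - 1]


def test_estimate_maf_basic_and_flip():
    dosages = np.array([[0.0, 2.0], [0.0, 2.0], [0.0, 1.0], [1.0, 2.0]])
    mafs, flipped = estimate_maf(dosages)
    np.testing.assert_allclose(mafs, [0.125, 0.125])
    assert list(flipped) == [False, True]


def test_estimate_maf_all_zero_column():
    mafs, flipped = estimate_maf(np.zeros((5, 1)))
    assert mafs[0] == 0.0 and not flipped[0]


def test_estimate_maf_all_missing_column_raises():
    d = np.array([[0.0, np.nan], [1.0, np.nan]])
    with pytest.raises(MissingDataError, match="1"):
        estimate_maf(d)


def test_filter_rare():
    v = pd.DataFrame({"variant_id": ["a", "b", "c"], "maf": [0.005, 0.02, 0.0]})
    kept = filter_rare(v)
    assert kept["variant_id"].tolist() == ["a"]
    assert filter_rare(v.iloc[:0]).empty
    allsame = pd.DataFrame({"variant_id": ["a", "b"], "maf": [0.009, 0.009]})
    assert len(filter_rare(allsame)) == 2


def test_multi_carrier_probability():
    assert round(multi_carrier_probability(50, 0.01), 4) == 0.0138
    assert multi_carrier_probability(2, 0.37) == 0.0
    assert multi_carrier_probability(3, 0.5) == pytest.approx(0.125)


def test_simulated_data_satisfies_decomposition_invariants():
    data = simulate_dataset(SimulationConfig(beta1=0.5, prop_causal=0.4, seed=3))
    gene = data.collapse()
    assert np.all(gene.ge[:, 0] == 0) and np.all(gene.d[:, 0] == 0)
    assert gene.d.min() >= -1 and gene.d.max() <= 1
    assert set(np.unique(gene.ge)) <= {0.0, 0.5, 1.0, 1.5, 2.0}
    # per-offspring index structure
    for j in range(gene.n_offspring):
        if gene.r[j] == 0:
            assert gene.s[j] == 0
        else:
            assert gene.d[j, gene.r[j]] != 0
        if gene.s[j] != 0:
            assert gene.mafs[gene.r[j] - 1] <= gene.mafs[gene.s[j] - 1]
    # GE consistency with parents
    for i, fam in enumerate(data.families):
        np.testing.assert_allclose(gene.ge[i, 1:], (fam.gm + fam.gf) / 2.0)


def test_collapsed_components_orthogonal(rng):
    # within/between components decorrelate: cov of the collapsed D-term and
    # GE-term is 0 within Monte-Carlo error over a large simulated sample
    data = simulate_dataset(
        SimulationConfig(n_families=4000, n_variants=10, maf=0.05, beta1=0.0,
                         beta2=0.0, seed=99)
    )
    gene = data.collapse()
    x1 = gene.d_r + gene.d_s
    x2 = gene.ge_r + gene.ge_s
    cov = np.mean((x1 - x1.mean()) * (x2 - x2.mean()))
    se = np.std((x1 - x1.mean()) * (x2 - x2.mean()), ddof=1) / np.sqrt(x1.size)
    assert abs(cov) < 3 * se


def test_mendelian_error_offspring_dropped(caplog):
    fam_ok = FamilyGenotypes("f1", gm=[1, 0], gf=[0, 0],
                             g=[[1, 0], [0, 0]], y=[0.1, 0.2])
    fam_bad = FamilyGenotypes("f2", gm=[0, 0], gf=[0, 0],
                              g=[[2, 0], [0, 0]], y=[0.3, 0.4])
    with caplog.at_level(logging.WARNING):
        gene = collapse_gene([fam_ok, fam_bad], mafs=[0.005, 0.006])
    assert gene.n_offspring == 3  # one impossible child removed
    assert any("Mendelian" in rec.message for rec in caplog.records)


def test_simulate_parents_requires_valid_maf(rng):
    with pytest.raises(ValueError):
        simulate_parents(5, 0.6, rng)
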