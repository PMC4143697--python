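"""Orthogonal within/between-family genotype decomposition and rare-variant collapsing.

Offspring genotypic scores (minor-allele counts) are split into the Mendelian
expectation given the parents, ``GE = (GM + GF) / 2`` — the between-family
component — and the transmission deviation ``D = G - GE`` — the within-family
component.  Because rare variants (MAF < 1%) almost never deviate at more
than two loci in one individual, each offspring is summarised by at most two
deviating loci, indexed ``r`` (smallest MAF) and ``s`` (second smallest),
with the pseudolocus 0 (``GE = D = 0``) standing in when fewer exist.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DimensionError, InvalidGenotypeError, MissingDataError

logger = logging.getLogger(__name__)

__all__ = [
    "FamilyGenotypes",
    "CollapsedGene",
    "expected_score",
    "deviation",
    "collapse_indices",
    "locus_rank",
    "estimate_maf",
    "filter_rare",
    "multi_carrier_probability",
    "mendelian_valid",
    "collapse_gene",
]


# ---------------------------------------------------------------------------
# elementary score operations


def _check_scores(a, name):
    a = np.asarray(a)
    if not np.isin(a, (0, 1, 2)).all():
        raise InvalidGenotypeError(
            f"{name} contains values outside {{0, 1, 2}}"
        )
    return a.astype(np.float64)


def expected_score(gm, gf):
    """Mendelian expectation of an offspring score: ``(GM + GF) / 2``.

    Accepts scalars or arrays of parental minor-allele counts in {0, 1, 2}.
    """
    gm = _check_scores(gm, "maternal score")
    gf = _check_scores(gf, "paternal score")
    return (gm + gf) / 2.0


def deviation(g, ge):
    """Transmission deviation ``D = G - GE`` of an offspring score."""
    g = _check_scores(g, "offspring score")
    return g - np.asarray(ge, dtype=np.float64)


def mendelian_valid(gm, gf, g):
    """Boolean mask of offspring scores consistent with the parental pair.

    A parent with score 0 transmits no minor allele, with score 2 always
    one, with score 1 either; the child count must lie between the forced
    minimum and the attainable maximum.
    """
    gm = np.asarray(gm)
    gf = np.asarray(gf)
    g = np.asarray(g)
    lo = (gm == 2).astype(int) + (gf == 2).astype(int)
    hi = (gm >= 1).astype(int) + (gf >= 1).astype(int)
    return (g >= lo) & (g <= hi)


# ---------------------------------------------------------------------------
# collapsing indices


def locus_rank(mafs, positions=None, variant_ids=None):
    """Deterministic rarity ranking of loci: by MAF, then genomic position,
    then variant id.  Rank 0 is the rarest locus."""
    mafs = np.asarray(mafs, dtype=np.float64)
    K = mafs.shape[0]
    if positions is None:
        positions = np.arange(K)
    if variant_ids is None:
        variant_ids = np.arange(K)
    order = np.lexsort((np.asarray(variant_ids), np.asarray(positions), mafs))
    rank = np.empty(K, dtype=np.int64)
    rank[order] = np.arange(K)
    return rank


def collapse_indices(d_row, mafs, positions=None, variant_ids=None):
    """Collapse one offspring's deviation vector to the pair ``(r, s)``.

    ``r`` is the 1-based index of the deviating locus with the smallest MAF,
    ``s`` the second smallest; 0 (the pseudolocus) when fewer than one or two
    loci deviate.  Ties are broken by genomic position, then variant id.
    """
    d_row = np.asarray(d_row, dtype=np.float64)
    mafs = np.asarray(mafs, dtype=np.float64)
    if d_row.shape != mafs.shape:
        raise DimensionError(
            f"deviation row has {d_row.shape[0]} loci but {mafs.shape[0]} MAFs given"
        )
    nz = np.flatnonzero(d_row != 0)
    if nz.size == 0:
        return 0, 0
    rank = locus_rank(mafs, positions, variant_ids)
    ordered = nz[np.argsort(rank[nz])]
    r = int(ordered[0]) + 1
    s = int(ordered[1]) + 1 if ordered.size > 1 else 0
    return r, s


# ---------------------------------------------------------------------------
# MAF estimation and filtering


def estimate_maf(dosages):
    """Per-locus MAF from a dosage matrix (individuals x loci, entries in
    [0, 2], NaN = missing).

    Returns ``(mafs, flipped)``.  Columns whose mean dosage / 2 exceeds 0.5
    are reported on the minor-allele convention (``1 - f``) with the flip
    flag set; callers should recode such columns as ``2 - dosage``.
    """
    dosages = np.asarray(dosages, dtype=np.float64)
    if dosages.ndim != 2:
        raise DimensionError("dosage matrix must be 2-dimensional")
    all_missing = np.isnan(dosages).all(axis=0)
    if all_missing.any():
        bad = np.flatnonzero(all_missing)
        raise MissingDataError(f"loci with no observed dosage: {bad.tolist()}")
    freq = np.nanmean(dosages, axis=0) / 2.0
    flipped = freq > 0.5
    mafs = np.where(flipped, 1.0 - freq, freq)
    return mafs, flipped


def filter_rare(variants: pd.DataFrame, threshold: float = 0.01) -> pd.DataFrame:
    """Keep polymorphic rare variants: ``0 < maf < threshold``.

    Monomorphic variants carry no information and would only inflate the
    locus count K entering the prior odds, so they are excluded even though
    a literal "MAF < 1%" would admit them.
    """
    maf = variants["maf"].to_numpy()
    return variants.loc[(maf > 0) & (maf < threshold)]


def multi_carrier_probability(K: int, carrier_prob: float) -> float:
    """P(X > 2) for X ~ Binomial(K, carrier_prob): the chance an individual
    carries minor alleles at more than two of K independent loci.

    This tail probability (≈1.38% at K=50, carrier probability 1%) is what
    justifies collapsing each offspring to at most two deviating loci.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if not 0.0 <= carrier_prob <= 1.0:
        raise ValueError("carrier_prob must lie in [0, 1]")
    return float(stats.binom.sf(2, K, carrier_prob))


# ---------------------------------------------------------------------------
# containers


@dataclass
class FamilyGenotypes:
    """Raw per-family data: both parents' scores, offspring score matrix,
    offspring phenotypes and optional covariates."""

    family_id: str
    gm: np.ndarray  # (K,) maternal scores in {0,1,2}
    gf: np.ndarray  # (K,) paternal scores
    g: np.ndarray   # (n_offspring, K) offspring scores
    y: np.ndarray   # (n_offspring,) quantitative phenotypes
    covariates: np.ndarray | None = None  # (n_offspring, P)
    offspring_ids: list[str] | None = None

    def __post_init__(self):
        self.gm = np.asarray(self.gm)
        self.gf = np.asarray(self.gf)
        self.g = np.atleast_2d(np.asarray(self.g))
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.g.shape[0] != self.y.shape[0]:
            raise DimensionError(
                f"family {self.family_id}: {self.g.shape[0]} offspring genotype rows "
                f"but {self.y.shape[0]} phenotypes"
            )
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=np.float64))
            if self.covariates.shape[0] != self.y.shape[0]:
                raise DimensionError(
                    f"family {self.family_id}: covariate rows do not match offspring"
                )
        if self.offspring_ids is None:
            self.offspring_ids = [
                f"{self.family_id}_o{j + 1}" for j in range(self.y.shape[0])
            ]

    @property
    def n_offspring(self) -> int:
        return self.g.shape[0]


@dataclass
class CollapsedGene:
    """A gene's collapsed family dataset ready for model fitting.

    Matrices carry the pseudolocus as column 0 (identically zero), so locus
    k of the gene is column k.  ``r`` and ``s`` index into these columns.
    """

    gene_id: str
    mafs: np.ndarray        # (K,) per-locus MAF, locus k -> mafs[k-1]
    ge: np.ndarray          # (M, K+1) expected scores per family
    d: np.ndarray           # (N, K+1) deviations per offspring
    fam_index: np.ndarray   # (N,) family row of each offspring
    r: np.ndarray           # (N,) smallest-MAF deviating locus, 0..K
    s: np.ndarray           # (N,) second smallest, 0..K
    y: np.ndarray | None = None           # (N,)
    covariates: np.ndarray | None = None  # (N, P)
    family_ids: list[str] = field(default_factory=list)
    offspring_ids: list[str] = field(default_factory=list)
    positions: np.ndarray | None = None   # (K,)
    variant_ids: list[str] | None = None

    def __post_init__(self):
        if np.any(self.ge[:, 0] != 0) or np.any(self.d[:, 0] != 0):
            raise ValueError("pseudolocus column 0 must be identically zero")

    @property
    def n_variants(self) -> int:
        return self.mafs.shape[0]

    @property
    def n_families(self) -> int:
        return self.ge.shape[0]

    @property
    def n_offspring(self) -> int:
        return self.d.shape[0]

    @property
    def informative(self) -> bool:
        """True when at least one offspring shows a transmission deviation.

        GE enters the model only at loci indexed by r/s, which are defined
        through deviations, so a gene with no deviation is inert."""
        return bool(np.any(self.r > 0))

    # gathered per-offspring values used by the sampler and for inspection
    @property
    def d_r(self) -> np.ndarray:
        return self.d[np.arange(self.n_offspring), self.r]

    @property
    def d_s(self) -> np.ndarray:
        return self.d[np.arange(self.n_offspring), self.s]

    @property
    def ge_r(self) -> np.ndarray:
        return self.ge[self.fam_index, self.r]

    @property
    def ge_s(self) -> np.ndarray:
        return self.ge[self.fam_index, self.s]

    def to_frame(self) -> pd.DataFrame:
        """Flat per-offspring view (family, offspring, r, s, D, GE, y, covariates)."""
        out = pd.DataFrame(
            {
                "family": [self.family_ids[i] for i in self.fam_index]
                if self.family_ids
                else self.fam_index,
                "offspring": self.offspring_ids
                if self.offspring_ids
                else np.arange(self.n_offspring),
                "r": self.r,
                "s": self.s,
                "D_r": self.d_r,
                "D_s": self.d_s,
                "GE_r": self.ge_r,
                "GE_s": self.ge_s,
            }
        )
        if self.y is not None:
            out["y"] = self.y
        if self.covariates is not None:
            for p in range(self.covariates.shape[1]):
                out[f"covariate_{p + 1}"] = self.covariates[:, p]
        return out

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene assembly


def collapse_gene(
    families: list[FamilyGenotypes],
    mafs,
    positions=None,
    variant_ids=None,
    gene_id: str = "gene",
    check_mendelian: bool = True,
) -> CollapsedGene:
    """Build the collapsed within/between-family representation of a gene.

    Offspring whose genotype is Mendelian-impossible given the parents are
    dropped with a logged warning.
    """
    mafs = np.asarray(mafs, dtype=np.float64)
    K = mafs.shape[0]
    rank = locus_rank(mafs, positions, variant_ids)

    ge_rows, d_rows, fam_idx = [], [], []
    y_rows, cov_rows = [], []
    family_ids, offspring_ids = [], []
    n_dropped = 0

    for fam in families:
        if fam.gm.shape[0] != K or fam.g.shape[1] != K:
            raise DimensionError(
                f"family {fam.family_id}: genotype width does not match {K} loci"
            )
        ge = expected_score(fam.gm, fam.gf)
        keep = np.ones(fam.n_offspring, dtype=bool)
        if check_mendelian:
            ok = mendelian_valid(fam.gm[None, :], fam.gf[None, :], fam.g).all(axis=1)
            for j in np.flatnonzero(~ok):
                logger.warning(
                    "dropping offspring %s of family %s: Mendelian-inconsistent genotype",
                    fam.offspring_ids[j],
                    fam.family_id,
                )
            n_dropped += int((~ok).sum())
            keep &= ok
        if not keep.any():
            continue
        g = _check_scores(fam.g[keep], "offspring score")
        d = g - ge[None, :]
        i = len(family_ids)
        family_ids.append(fam.family_id)
        ge_rows.append(ge)
        d_rows.append(d)
        fam_idx.append(np.full(d.shape[0], i))
        y_rows.append(fam.y[keep])
        if fam.covariates is not None:
            cov_rows.append(fam.covariates[keep])
        offspring_ids.extend(np.asarray(fam.offspring_ids, dtype=object)[keep])

    if not ge_rows:
        ge = np.zeros((0, K + 1))
        d = np.zeros((0, K + 1))
        return CollapsedGene(
            gene_id, mafs, ge, d,
            np.zeros(0, dtype=np.int64),
            np.zeros(0, dtype=np.int64),
            np.zeros(0, dtype=np.int64),
            y=np.zeros(0), covariates=None,
            family_ids=[], offspring_ids=[],
            positions=None if positions is None else np.asarray(positions),
            variant_ids=list(variant_ids) if variant_ids is not None else None,
        )

    ge_mat = np.hstack([np.zeros((len(ge_rows), 1)), np.vstack(ge_rows)])
    d_all = np.vstack(d_rows)
    d_mat = np.hstack([np.zeros((d_all.shape[0], 1)), d_all])
    fam_index = np.concatenate(fam_idx).astype(np.int64)
    y = np.concatenate(y_rows)
    covariates = np.vstack(cov_rows) if cov_rows else None

    # vectorised (r, s): rarity rank where deviating, +inf elsewhere
    score = np.where(d_all != 0, rank[None, :].astype(np.float64), np.inf)
    r = np.zeros(d_all.shape[0], dtype=np.int64)
    s = np.zeros(d_all.shape[0], dtype=np.int64)
    if d_all.shape[0]:
        first = np.argmin(score, axis=1)
        has1 = np.isfinite(score[np.arange(score.shape[0]), first])
        r[has1] = first[has1] + 1
        score2 = score.copy()
        score2[np.arange(score.shape[0]), first] = np.inf
        second = np.argmin(score2, axis=1)
        has2 = np.isfinite(score2[np.arange(score.shape[0]), second]) & has1
        s[has2] = second[has2] + 1

    if n_dropped:
        logger.warning(
            "gene %s: dropped %d Mendelian-inconsistent offspring", gene_id, n_dropped
        )

    return CollapsedGene(
        gene_id=gene_id,
        mafs=mafs,
        ge=ge_mat,
        d=d_mat,
        fam_index=fam_index,
        r=r,
        s=s,
        y=y,
        covariates=covariates,
        family_ids=family_ids,
        offspring_ids=list(offspring_ids),
        positions=None if positions is None else np.asarray(positions),
        variant_ids=list(variant_ids) if variant_ids is not None else None,
    )
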