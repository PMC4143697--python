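"""File ingestion, phenotype preprocessing and study assembly.

Reads VCF (GT or DS), 6-column PED/FAM, a visit-level phenotype TSV
(individual_id, visit, measurement, age) and BED gene intervals; assembles
nuclear families (offspring with both parents genotyped) and applies the
exclusion rules: any offspring with a missing genotype, a missing
phenotype or an ungenotyped parent is excluded, with counts kept so no
exclusion is silent.

Coordinates are BED-style half-open 0-based internally; VCF positions are
converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import MissingDataError
from .pedigree import CollapsedGene, FamilyGenotypes, collapse_gene, estimate_maf, filter_rare

logger = logging.getLogger(__name__)

__all__ = [
    "Study",
    "NuclearFamily",
    "preprocess_phenotype",
    "read_vcf",
    "read_ped",
    "read_bed",
    "load_study",
    "build_gene_dataset",
    "study_from_tables",
    "study_from_simulation",
    "write_study_files",
    "ld_prune",
]

PED_COLUMNS = ["family_id", "individual_id", "father", "mother", "sex", "phenotype"]


# ---------------------------------------------------------------------------
# phenotype preprocessing


def preprocess_phenotype(visits: pd.DataFrame) -> pd.DataFrame:
    """Collapse repeated visit measurements to one (phenotype, age) pair
    per individual.

    The phenotype is the natural log of the individual's highest
    measurement across visits (log fixes the right skew of blood-pressure
    style traits); the covariate is the age at that highest measurement,
    taking the earliest such age when the maximum is tied.  Individuals
    with no non-missing measurement are excluded with a log entry.
    """
    required = {"individual_id", "measurement", "age"}
    missing = required - set(visits.columns)
    if missing:
        raise ValueError(f"phenotype table lacks columns: {sorted(missing)}")
    rows = []
    excluded = []
    for ind, grp in visits.groupby("individual_id", sort=False):
        grp = grp.dropna(subset=["measurement"])
        if grp.empty:
            excluded.append(ind)
            continue
        mx = grp["measurement"].max()
        if mx <= 0:
            raise ValueError(f"individual {ind}: non-positive measurement {mx}")
        age = grp.loc[grp["measurement"] == mx, "age"].min()
        rows.append((ind, float(np.log(mx)), float(age)))
    if excluded:
        logger.info("excluded %d individuals with no usable measurement: %s",
                    len(excluded), excluded[:10])
    out = pd.DataFrame(rows, columns=["individual_id", "phenotype", "age"])
    return out.set_index("individual_id")


# ---------------------------------------------------------------------------
# readers


def read_vcf(path):
    """Read a VCF into (samples, variants DataFrame, dosage matrix).

    Dosage is the minor-allele count per sample: the DS FORMAT field when
    present, otherwise the GT-derived allele count; missing genotypes
    become NaN.  Multi-allelic records are rejected (split them upstream).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    var_rows = []
    dosage_rows = []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {v.CHROM}:{v.POS}; split upstream"
            )
        try:
            ds = v.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            row = np.asarray(ds, dtype=np.float64).reshape(-1)
        else:
            row = np.asarray(v.gt_types, dtype=np.float64)
            row[row == 3] = np.nan  # gts012: 3 == unknown
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        var_rows.append((vid, str(v.CHROM), int(v.POS)))
        dosage_rows.append(row)
    variants = pd.DataFrame(var_rows, columns=["variant_id", "chrom", "pos"])
    dosage = (np.vstack(dosage_rows).T if dosage_rows
              else np.zeros((len(samples), 0)))
    return samples, variants, dosage


def read_ped(path) -> pd.DataFrame:
    """Read a 6-column PED/FAM file ('0' marks a missing parent)."""
    ped = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
    if ped.shape[1] < 6:
        raise ValueError(f"{path}: PED needs 6 columns, found {ped.shape[1]}")
    ped = ped.iloc[:, :6]
    ped.columns = PED_COLUMNS
    dup = ped["individual_id"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate individual ids in PED: "
                         f"{ped.loc[dup, 'individual_id'].tolist()}")
    self_parent = (ped["individual_id"] == ped["father"]) | (
        ped["individual_id"] == ped["mother"])
    if self_parent.any():
        raise ValueError("pedigree cycle: individual listed as own parent")
    return ped


def read_bed(path) -> pd.DataFrame:
    """Read gene intervals from BED (0-based half-open; name = gene id)."""
    genes = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if genes.shape[1] < 4:
        raise ValueError(f"{path}: BED needs 4 columns (chrom start end name)")
    genes = genes.iloc[:, :4]
    genes.columns = ["chrom", "start", "end", "gene_id"]
    genes["start"] = genes["start"].astype(int)
    genes["end"] = genes["end"].astype(int)
    return genes[["gene_id", "chrom", "start", "end"]]


# ---------------------------------------------------------------------------
# study assembly


@dataclass
class NuclearFamily:
    family_id: str
    father: str
    mother: str
    children: list


@dataclass
class Study:
    """Loaded study: genotypes on the minor-allele convention, assembled
    nuclear families, per-individual phenotype and age."""

    samples: list
    variants: pd.DataFrame          # variant_id, chrom, pos, maf, flipped
    dosage: np.ndarray              # (n_samples, n_variants), NaN = missing
    genes: pd.DataFrame             # gene_id, chrom, start, end
    families: list
    phenotypes: pd.DataFrame        # index individual_id: phenotype, age
    exclusions: dict = field(default_factory=dict)
    use_age_covariate: bool = True

    def sample_index(self, individual_id: str) -> int:
        return self._sample_pos[individual_id]

    def __post_init__(self):
        self._sample_pos = {s: i for i, s in enumerate(self.samples)}


def _assemble_families(ped: pd.DataFrame, samples, phenotypes: pd.DataFrame):
    sample_set = set(samples)
    pheno_set = set(phenotypes.index)
    groups = {}
    excl = {
        "children_in_ped": 0,
        "kept": 0,
        "missing_parent_id": 0,
        "parent_not_genotyped": 0,
        "child_not_genotyped": 0,
        "child_no_phenotype": 0,
    }
    for row in ped.itertuples(index=False):
        if row.father == "0" or row.mother == "0":
            continue  # founder / not an offspring record
        excl["children_in_ped"] += 1
        if row.father not in sample_set or row.mother not in sample_set:
            excl["parent_not_genotyped"] += 1
            continue
        if row.individual_id not in sample_set:
            excl["child_not_genotyped"] += 1
            continue
        if row.individual_id not in pheno_set:
            excl["child_no_phenotype"] += 1
            continue
        key = (row.family_id, row.father, row.mother)
        groups.setdefault(key, []).append(row.individual_id)
        excl["kept"] += 1
    families = [
        NuclearFamily(
            family_id=fid if len({k for k in groups if k[0] == fid}) == 1
            else f"{fid}:{fa}x{mo}",
            father=fa, mother=mo, children=children,
        )
        for (fid, fa, mo), children in groups.items()
    ]
    logger.info("family assembly: %s", excl)
    return families, excl


def study_from_tables(samples, variants: pd.DataFrame, dosage, ped: pd.DataFrame,
                      visits: pd.DataFrame, genes: pd.DataFrame,
                      use_age_covariate: bool = True,
                      ld_r2: float | None = None) -> Study:
    """Assemble a :class:`Study` from in-memory tables (shared by the file
    loader and the simulator bridge)."""
    dosage = np.asarray(dosage, dtype=np.float64)
    mafs, flipped = estimate_maf(dosage)
    dosage = dosage.copy()
    if flipped.any():
        dosage[:, flipped] = 2.0 - dosage[:, flipped]
        logger.info("flipped %d variants to the minor-allele convention",
                    int(flipped.sum()))
    variants = variants.copy()
    variants["maf"] = mafs
    variants["flipped"] = flipped
    phenotypes = preprocess_phenotype(visits)
    families, excl = _assemble_families(ped, samples, phenotypes)
    study = Study(
        samples=list(samples), variants=variants, dosage=dosage,
        genes=genes.reset_index(drop=True), families=families,
        phenotypes=phenotypes, exclusions=excl,
        use_age_covariate=use_age_covariate,
    )
    if ld_r2 is not None:
        keep = ld_prune(study.dosage, variants, r2_threshold=ld_r2)
        study.variants = variants.loc[keep].reset_index(drop=True)
        study.dosage = study.dosage[:, keep]
    return study


def load_study(vcf_path, ped_path, phenotype_path, genes_path,
               use_age_covariate: bool = True,
               ld_r2: float | None = None) -> Study:
    """Load a study from VCF + PED + phenotype TSV + BED files."""
    samples, variants, dosage = read_vcf(vcf_path)
    ped = read_ped(ped_path)
    visits = pd.read_csv(phenotype_path, sep="\t", dtype={"individual_id": str},
                         float_precision="round_trip")
    genes = read_bed(genes_path)
    return study_from_tables(samples, variants, dosage, ped, visits, genes,
                             use_age_covariate=use_age_covariate, ld_r2=ld_r2)


def ld_prune(dosage, variants: pd.DataFrame, r2_threshold: float = 0.8):
    """Greedy pruning to 'independent representative' variants.

    Variants are visited rarest first (MAF, then position); a variant is
    kept only if its squared correlation with every already-kept variant
    stays at or below the threshold.  Returns the kept column indices in
    position order.
    """
    maf = variants["maf"].to_numpy()
    pos = variants["pos"].to_numpy()
    order = np.lexsort((pos, maf))
    df = pd.DataFrame(dosage)
    kept = []
    for j in order:
        ok = True
        for k in kept:
            r = df[j].corr(df[k])
            if np.isfinite(r) and r * r > r2_threshold:
                ok = False
                break
        if ok:
            kept.append(j)
    return sorted(kept)


# ---------------------------------------------------------------------------
# per-gene dataset construction


def build_gene_dataset(study: Study, gene_row, maf_threshold: float = 0.01):
    """Collapse one gene: rare-variant filter, family construction with
    the exclusion rules, Mendelian screening, (r, s) indices.

    Returns ``(CollapsedGene | None, status)`` with status one of
    ``ok``, ``skipped_no_variants``, ``skipped_no_information``.
    A variant belongs to every gene whose interval contains it.
    """
    v = study.variants
    pos0 = v["pos"].to_numpy() - 1  # VCF 1-based -> half-open 0-based
    in_gene = (
        (v["chrom"].to_numpy() == gene_row["chrom"])
        & (pos0 >= gene_row["start"])
        & (pos0 < gene_row["end"])
    )
    sub = filter_rare(v.loc[in_gene], threshold=maf_threshold)
    if sub.empty:
        return None, "skipped_no_variants"
    sub = sub.sort_values("pos", kind="stable")
    cols = sub.index.to_numpy()
    mafs = sub["maf"].to_numpy()
    positions = sub["pos"].to_numpy()
    vids = sub["variant_id"].tolist()

    fams = []
    for fam in study.families:
        fa = study.dosage[study.sample_index(fam.father), cols]
        mo = study.dosage[study.sample_index(fam.mother), cols]
        if np.isnan(fa).any() or np.isnan(mo).any():
            continue  # offspring without complete parental information
        gm = np.clip(np.rint(mo), 0, 2).astype(np.int64)
        gf = np.clip(np.rint(fa), 0, 2).astype(np.int64)
        g_rows, y_rows, cov_rows, kids = [], [], [], []
        for child in fam.children:
            cg = study.dosage[study.sample_index(child), cols]
            if np.isnan(cg).any():
                continue
            g_rows.append(np.clip(np.rint(cg), 0, 2).astype(np.int64))
            rec = study.phenotypes.loc[child]
            y_rows.append(float(rec["phenotype"]))
            cov_rows.append([float(rec["age"])])
            kids.append(child)
        if not g_rows:
            continue
        fams.append(FamilyGenotypes(
            family_id=fam.family_id, gm=gm, gf=gf,
            g=np.vstack(g_rows), y=np.array(y_rows),
            covariates=np.array(cov_rows) if study.use_age_covariate else None,
            offspring_ids=kids,
        ))
    gene = collapse_gene(fams, mafs, positions=positions, variant_ids=vids,
                         gene_id=gene_row["gene_id"])
    if gene.n_offspring == 0 or not gene.informative:
        return gene, "skipped_no_information"
    return gene, "ok"


# ---------------------------------------------------------------------------
# simulator bridge and writers


def study_from_simulation(data, chrom: str = "1", first_pos: int = 1001,
                          spacing: int = 100, gene_id: str = "SIMGENE"):
    """Turn a :class:`~fbcm.simulate.SimulatedData` replicate into the raw
    study tables (samples, variants, genotype matrix, PED, visit table,
    genes).

    Ages are synthetic, a deterministic function of the offspring index,
    so that the in-memory path and the file round-trip produce identical
    model inputs.  Returns ``(tables, study)`` where ``tables`` can be
    written with :func:`write_study_files` and ``study`` is the assembled
    in-memory :class:`Study`.
    """
    K = data.config.n_variants
    samples, geno_rows, ped_rows, visit_rows = [], [], [], []
    child_counter = 0
    for fam in data.families:
        fid = fam.family_id
        father, mother = f"{fid}_P1", f"{fid}_P2"
        samples += [father, mother]
        geno_rows += [fam.gf, fam.gm]
        ped_rows += [
            (fid, father, "0", "0", "1", "-9"),
            (fid, mother, "0", "0", "2", "-9"),
        ]
        for j in range(fam.n_offspring):
            cid = fam.offspring_ids[j]
            samples.append(cid)
            geno_rows.append(fam.g[j])
            ped_rows.append((fid, cid, father, mother, "0", "-9"))
            age = 40.0 + (child_counter % 20)
            visit_rows.append((cid, 1, float(np.exp(fam.y[j])), age))
            child_counter += 1
    geno = np.vstack(geno_rows)
    positions = first_pos + spacing * np.arange(K)
    variants = pd.DataFrame({
        "variant_id": [f"sv{k + 1}" for k in range(K)],
        "chrom": chrom,
        "pos": positions,
    })
    ped = pd.DataFrame(ped_rows, columns=PED_COLUMNS)
    visits = pd.DataFrame(visit_rows,
                          columns=["individual_id", "visit", "measurement", "age"])
    genes = pd.DataFrame({
        "gene_id": [gene_id], "chrom": [chrom],
        "start": [0], "end": [int(positions[-1]) + spacing],
    })
    tables = dict(samples=samples, variants=variants, genotypes=geno,
                  ped=ped, visits=visits, genes=genes)
    study = study_from_tables(samples, variants, geno.astype(np.float64),
                              ped, visits, genes)
    return tables, study


_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(path, samples, variants: pd.DataFrame, genotypes) -> None:
    """Write integer genotypes as a minimal VCF 4.2 with GT fields."""
    genotypes = np.asarray(genotypes)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for j, row in enumerate(variants.itertuples(index=False)):
            calls = "\t".join(
                _GT.get(int(g), "./.") if not np.isnan(g) else "./."
                for g in genotypes[:, j].astype(np.float64)
            )
            fh.write(f"{row.chrom}\t{row.pos}\t{row.variant_id}\tA\tT\t.\tPASS\t.\tGT\t{calls}\n")


def write_study_files(tables: dict, outdir) -> dict:
    """Write a simulated study as VCF + PED + phenotype TSV + BED.

    Floats are written with 17 significant digits so the file round trip
    is bit-exact.  Returns the paths written.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "study.vcf",
        "ped": outdir / "study.ped",
        "phenotype": outdir / "phenotypes.tsv",
        "genes": outdir / "genes.bed",
    }
    write_vcf(paths["vcf"], tables["samples"], tables["variants"],
              tables["genotypes"])
    tables["ped"].to_csv(paths["ped"], sep="\t", header=False, index=False)
    tables["visits"].to_csv(paths["phenotype"], sep="\t", index=False,
                            float_format="%.17g")
    genes = tables["genes"]
    genes[["chrom", "start", "end", "gene_id"]].to_csv(
        paths["genes"], sep="\t", header=False, index=False)
    return paths
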