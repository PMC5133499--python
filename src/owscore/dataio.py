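"""Genotype and phenotype input, region filtering, and sample alignment.

Genotypes are read either from VCF 4.x (plain or bgzipped, via cyvcf2) or
from a tab-delimited samples-by-variants dosage matrix.  Dosages are always
recoded to count the minor allele of the loaded sample, so downstream
statistics see rare-allele counts regardless of how the file coded REF/ALT.

Analysis is complete-case: :func:`align_samples` intersects the genotype,
phenotype, and pedigree sources, drops any individual with a missing value,
and restricts the kinship blocks to the retained individuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EmptyIntersectionError, RegionError
from .pedigree import KinshipBlocks, Pedigree, phi_blocks

logger = logging.getLogger(__name__)

NA_TOKEN = "NA"


@dataclass
class GenotypeMatrix:
    """Individuals-by-variants dosage matrix with per-variant metadata.

    ``dosages`` holds counts of the coded (minor) allele in {0,1,2}; NaN marks
    a missing genotype until complete-case filtering removes the individual.
    ``variant_meta`` has columns id, chrom, pos (1-based), coded_allele.
    """

    dosages: np.ndarray  # (n_samples, n_variants), float
    variant_meta: pd.DataFrame
    sample_ids: list[str]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def subset_samples(self, keep_ids: Sequence[str]) -> "GenotypeMatrix":
        index = {iid: k for k, iid in enumerate(self.sample_ids)}
        rows = [index[iid] for iid in keep_ids]
        return GenotypeMatrix(
            self.dosages[rows, :], self.variant_meta.copy(), list(keep_ids)
        )

    def subset_variants(self, cols: Sequence[int]) -> "GenotypeMatrix":
        cols = list(cols)
        return GenotypeMatrix(
            self.dosages[:, cols],
            self.variant_meta.iloc[cols].reset_index(drop=True),
            list(self.sample_ids),
        )


@dataclass
class PhenotypeTable:
    """Per-individual trait measurements and covariates, keyed by individual ID."""

    data: pd.DataFrame  # index: individual_id; numeric columns

    @property
    def sample_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    def subset_samples(self, keep_ids: Sequence[str]) -> "PhenotypeTable":
        return PhenotypeTable(self.data.loc[list(keep_ids)].copy())


def _recode_to_minor(dosages: np.ndarray, meta: pd.DataFrame) -> np.ndarray:
    """Flip coding (g -> 2 - g) for variants whose coded allele is the major one.

    The coded allele is major when its mean dosage exceeds 1 among observed
    genotypes; exact 0.5 frequency is left as coded.
    """
    out = dosages.copy()
    for m in range(out.shape[1]):
        col = out[:, m]
        obs = col[~np.isnan(col)]
        if obs.size and obs.sum() > obs.size:  # allele frequency > 0.5
            out[:, m] = 2.0 - col
            ref = meta.at[m, "coded_allele"]
            meta.at[m, "coded_allele"] = f"flip({ref})"
            logger.info(
                "variant %s: coded allele was major; recoded to its complement",
                meta.at[m, "id"],
            )
    return out


def _read_vcf(path, region=None) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            logger.warning(
                "skipping non-biallelic record %s:%d (%d ALT alleles)",
                var.CHROM, var.POS, len(var.ALT),
            )
            continue
        if region is not None:
            chrom, start, end = region
            if str(var.CHROM) != str(chrom) or not (start <= var.POS <= end):
                continue
        dos = np.empty(len(samples))
        for k, gt in enumerate(var.genotypes):  # [allele1, allele2, phased]
            alleles = [a for a in gt[:-1] if a >= 0]
            dos[k] = float(sum(alleles)) if len(alleles) == 2 else np.nan
        rows.append(dos)
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        meta.append((vid, str(var.CHROM), int(var.POS), var.ALT[0]))
    dosages = np.array(rows).T if rows else np.zeros((len(samples), 0))
    meta_df = pd.DataFrame(meta, columns=["id", "chrom", "pos", "coded_allele"])
    return dosages, meta_df, samples


def _read_dosage_tsv(path) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN], comment="#")
    dosages = df.to_numpy(dtype=float)
    meta = pd.DataFrame(
        {
            "id": [str(c) for c in df.columns],
            "chrom": ".",
            "pos": np.arange(1, df.shape[1] + 1),  # column order stands in for position
            "coded_allele": "ALT",
        }
    )
    return dosages, meta, [str(i) for i in df.index]


def read_genotypes(path, region: tuple | None = None) -> GenotypeMatrix:
    """Read genotype dosages from VCF or a samples-by-variants TSV.

    Parameters
    ----------
    path
        ``.vcf``/``.vcf.gz`` for VCF; anything else is parsed as a TSV dosage
        matrix (rows: samples, header: variant IDs, missing token "NA").
    region
        Optional ``(chrom, start, end)``, 1-based inclusive on both ends.
        Only applicable to positional (VCF) input.

    Non-biallelic VCF records are skipped with a warning.  Dosages are recoded
    to minor-allele counts (see module docstring).
    """
    name = str(path)
    if name.endswith((".vcf", ".vcf.gz", ".vcf.bgz")):
        dosages, meta, samples = _read_vcf(path, region)
    else:
        dosages, meta, samples = _read_dosage_tsv(path)
        if region is not None:
            raise RegionError(
                "region filtering requires positional input (VCF); "
                "use a variant-ID list for TSV matrices"
            )
    if region is not None and meta.shape[0] == 0:
        raise RegionError(f"region {region} contains no variants")
    if dosages.shape[1] == 0 and region is None:
        raise RegionError(f"{path}: no biallelic variants found")

    valid = np.isnan(dosages) | np.isin(dosages, (0.0, 1.0, 2.0))
    if not valid.all():
        raise ValueError(f"{path}: dosages must be 0, 1, 2 or missing")
    dosages = _recode_to_minor(dosages, meta)
    return GenotypeMatrix(dosages, meta, samples)


def filter_region(geno: GenotypeMatrix, region: tuple) -> GenotypeMatrix:
    """Keep variants inside (chrom, start, end), 1-based inclusive."""
    chrom, start, end = region
    meta = geno.variant_meta
    mask = (meta["chrom"].astype(str) == str(chrom)) & meta["pos"].between(start, end)
    cols = np.flatnonzero(mask.to_numpy())
    if cols.size == 0:
        raise RegionError(f"region {region} contains no variants")
    return geno.subset_variants(cols)


def filter_variant_ids(geno: GenotypeMatrix, ids: Sequence[str]) -> GenotypeMatrix:
    wanted = set(map(str, ids))
    cols = [k for k, v in enumerate(geno.variant_meta["id"]) if str(v) in wanted]
    if not cols:
        raise RegionError("variant-ID filter matched no variants")
    return geno.subset_variants(cols)


def filter_max_maf(geno: GenotypeMatrix, max_maf: float) -> GenotypeMatrix:
    """Keep variants with sample minor-allele frequency <= max_maf."""
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(geno.dosages, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    cols = np.flatnonzero(maf <= max_maf)
    if cols.size == 0:
        raise RegionError(f"no variants with MAF <= {max_maf}")
    return geno.subset_variants(cols)


def read_phenotypes(path) -> PhenotypeTable:
    """Read a phenotype/covariate TSV keyed by its first (individual_id) column."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN], comment="#")
    df.index = df.index.map(str)
    return PhenotypeTable(df)


def align_samples(
    geno: GenotypeMatrix,
    pheno: PhenotypeTable,
    peds: Sequence[Pedigree],
    columns: Sequence[str] | None = None,
) -> tuple[GenotypeMatrix, PhenotypeTable, list[Pedigree], KinshipBlocks]:
    """Complete-case intersection of genotype, phenotype, and pedigree sources.

    Retains individuals that appear in all three sources with no missing
    genotype and no missing value in the phenotype columns of interest
    (``columns``; default: all).  The canonical order is pedigree order
    (families in input order, members founders-first).  Kinship is computed on
    the *full* pedigrees and then restricted to the retained individuals, so
    relationships mediated by dropped members remain correct.
    """
    cols = list(columns) if columns is not None else list(pheno.data.columns)
    complete_geno = {
        iid
        for iid, row_ok in zip(geno.sample_ids, ~np.isnan(geno.dosages).any(axis=1))
        if row_ok
    }
    pdat = pheno.data[cols]
    complete_pheno = {str(i) for i in pdat.index[~pdat.isna().any(axis=1)]}

    keep = complete_geno & complete_pheno
    analyzed: list[str] = []
    for ped in peds:
        analyzed.extend(iid for iid in ped.ids if iid in keep)
    if not analyzed:
        raise EmptyIntersectionError(
            "no individual is present and complete in genotypes, phenotypes, "
            "and pedigrees"
        )
    logger.info("analyzed sample: %d individuals (complete cases)", len(analyzed))

    phi = phi_blocks(peds).subset(analyzed)
    return (
        geno.subset_samples(analyzed),
        pheno.subset_samples(analyzed),
        list(peds),
        phi,
    )
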