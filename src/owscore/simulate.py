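"""Synthetic pedigree studies: founder genotypes, gene dropping, traits.

The generator emulates a family sequencing study of the scale analyzed in
large blood-pressure workshops: ~20 multi-generation pedigrees totalling
~850 members, regions of 100 rare variants, and a quantitative trait with
covariate effects and a kinship-structured polygenic component.  Founder
haplotypes are drawn under Hardy-Weinberg equilibrium at specified minor
allele frequencies; descendants receive alleles by Mendelian gene dropping
(one allele from each parent, uniformly per meiosis per variant).

The trait model for individual j of family i is

    y_ij = a + sum_causal beta_m g_ijm + c' z_ij + p_ij + e_ij,

where p_i ~ MVN(0, h2 * sigma^2 * Phi_i) is the polygenic term,
e_ij ~ N(0, (1 - h2) * sigma^2), and z_ij the generated covariates.  With
h2 = 0 and no covariates this reduces to the plain normal-given-genotype
model; variance explained by beta is additional to sigma^2.

All randomness flows from explicit seeds: identical config + seed gives a
bitwise-identical study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dataio import GenotypeMatrix, PhenotypeTable
from .errors import AscertainmentError, SimulationError
from .pedigree import KinshipBlocks, Member, Pedigree, phi_blocks

COVARIATE_NAMES = ("sex", "age", "bp_med", "smoking")
# Modest fixed covariate effects in trait-SD units (age per year); regressed
# out before testing, so their exact values only exercise the adjustment.
DEFAULT_COVARIATE_EFFECTS = {"sex": 0.5, "age": 0.02, "bp_med": 0.3, "smoking": 0.4}


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic generator.

    Defaults are the family-study emulation preset: 20 pedigrees of 44
    members (four generations, sibships 3/3/2 with married-in founder
    spouses, 880 individuals total), 100 variants with MAF ~ U(0.001, 0.05),
    polygenic heritability 0.3, total trait SD 1, four covariates, no causal
    variants (a null block).
    """

    n_pedigrees: int = 20
    sibships: tuple[int, ...] = (3, 3, 2)
    n_variants: int = 100
    maf_low: float = 0.001
    maf_high: float = 0.05
    maf_values: np.ndarray | None = None  # fixed per-variant MAFs (overrides range)
    causal_indices: tuple[int, ...] = ()
    beta: tuple[float, ...] = ()  # trait units per coded allele, one per causal index
    h2_polygenic: float = 0.3
    sigma_total: float = 1.0
    intercept: float = 0.0
    with_covariates: bool = True
    covariate_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    ascertainment: str = "random"  # or "proband_extreme"
    proband_quantile: float = 0.9

    def __post_init__(self):
        if not 0.0 <= self.h2_polygenic < 1.0:
            raise SimulationError("h2_polygenic must lie in [0, 1)")
        if self.sigma_total <= 0:
            raise SimulationError("sigma_total must be positive")
        if len(self.causal_indices) != len(self.beta):
            raise SimulationError("causal_indices and beta must have equal length")
        if any(not 0 <= k < self.n_variants for k in self.causal_indices):
            raise SimulationError("causal_indices out of range")
        if self.ascertainment not in ("random", "proband_extreme"):
            raise SimulationError(f"unknown ascertainment rule {self.ascertainment!r}")


def gaw19_emulation_preset(**overrides) -> SimulationConfig:
    """The default study-scale preset (see class docstring), with overrides."""
    return SimulationConfig(**overrides)


def template_pedigree(family_id: str, sibships: Sequence[int] = (3, 3, 2)) -> Pedigree:
    """Build one multi-generation template family.

    Starts from a founder couple; in every generation but the last, each
    child marries a founder spouse and the couple has ``sibships[g]``
    children.  The default (3, 3, 2) yields a 44-member, four-generation
    pedigree.  Individual IDs are globally unique (prefixed by family ID).
    """
    members: list[Member] = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"{family_id}_{counter:03d}"

    def add(father, mother, sex) -> str:
        iid = new_id()
        members.append(Member(family_id, iid, father, mother, sex))
        return iid

    pa, ma = add(None, None, "male"), add(None, None, "female")
    couples = [(pa, ma)]
    for g, n_children in enumerate(sibships):
        last = g == len(sibships) - 1
        next_couples = []
        for father, mother in couples:
            for c in range(n_children):
                sex = "male" if c % 2 == 0 else "female"
                child = add(father, mother, sex)
                if not last:
                    spouse_sex = "female" if sex == "male" else "male"
                    spouse = add(None, None, spouse_sex)
                    parents = (child, spouse) if sex == "male" else (spouse, child)
                    next_couples.append(parents)
        couples = next_couples
    return Pedigree(family_id, members)


def study_pedigrees(config: SimulationConfig) -> list[Pedigree]:
    """The study's families: n_pedigrees copies of the template."""
    return [
        template_pedigree(f"P{k + 1:02d}", config.sibships)
        for k in range(config.n_pedigrees)
    ]


def draw_mafs(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if config.maf_values is not None:
        maf = np.asarray(config.maf_values, dtype=float)
        if maf.size != config.n_variants:
            raise SimulationError("maf_values length must equal n_variants")
    else:
        maf = rng.uniform(config.maf_low, config.maf_high, size=config.n_variants)
    if np.any((maf <= 0) | (maf > 0.5)):
        raise SimulationError("each MAF must lie in (0, 0.5]")
    return maf


def draw_founder_genotypes(
    maf: np.ndarray, n_founders: int, rng: np.random.Generator
) -> np.ndarray:
    """Founder dosages as two independent Hardy-Weinberg allele draws per variant."""
    maf = np.asarray(maf, dtype=float)
    if np.any((maf <= 0) | (maf > 0.5)):
        raise SimulationError("each MAF must lie in (0, 0.5]")
    return rng.binomial(2, maf, size=(n_founders, maf.size)).astype(float)


def gene_drop(
    ped: Pedigree, founder_genotypes: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Drop founder alleles through the pedigree by Mendelian transmission.

    ``founder_genotypes`` rows must match ``ped.founders`` in order.  Each
    non-founder receives one allele from each parent, chosen uniformly and
    independently per variant per meiosis.  Returns the dosage matrix for
    all members in pedigree order.
    """
    founders = ped.founders
    F = np.asarray(founder_genotypes, dtype=float)
    if F.shape[0] != len(founders):
        raise SimulationError(
            f"founder genotype rows ({F.shape[0]}) != founder count ({len(founders)})"
        )
    M = F.shape[1]
    index = {m.individual_id: k for k, m in enumerate(ped.members)}
    # Paternal/maternal allele indicators; dosage 1 stored as (0, 1) — which
    # slot carries the copy is irrelevant because transmission picks a slot
    # uniformly at random.
    A1 = np.zeros((len(ped), M))
    A2 = np.zeros((len(ped), M))
    f_iter = iter(range(len(founders)))
    for k, m in enumerate(ped.members):
        if m.is_founder:
            d = F[next(f_iter)]
            A1[k] = (d == 2).astype(float)
            A2[k] = (d >= 1).astype(float)
        else:
            p, q = index[m.father_id], index[m.mother_id]
            pick_p = rng.integers(0, 2, size=M).astype(bool)
            pick_q = rng.integers(0, 2, size=M).astype(bool)
            A1[k] = np.where(pick_p, A2[p], A1[p])
            A2[k] = np.where(pick_q, A2[q], A1[q])
    return A1 + A2


def drop_study_genotypes(
    peds: Sequence[Pedigree], maf: np.ndarray, rng: np.random.Generator
) -> GenotypeMatrix:
    """Founder draws + gene drop for every family, stacked in pedigree order."""
    blocks, ids = [], []
    for ped in peds:
        F = draw_founder_genotypes(maf, len(ped.founders), rng)
        blocks.append(gene_drop(ped, F, rng))
        ids.extend(ped.ids)
    dosages = np.vstack(blocks)
    meta = pd.DataFrame(
        {
            "id": [f"var{m + 1:04d}" for m in range(maf.size)],
            "chrom": "1",
            "pos": np.arange(1, maf.size + 1),
            "coded_allele": "A",
        }
    )
    return GenotypeMatrix(dosages, meta, ids)


def draw_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """The four-covariate design: binary sex, continuous age, two binaries."""
    return pd.DataFrame(
        {
            "sex": rng.integers(0, 2, size=n).astype(float),
            "age": rng.normal(50.0, 10.0, size=n),
            "bp_med": (rng.random(n) < 0.3).astype(float),
            "smoking": (rng.random(n) < 0.25).astype(float),
        }
    )


def polygenic_effects(
    phi: KinshipBlocks,
    h2: float,
    sigma_total: float,
    rng: np.random.Generator,
    size: int | None = None,
) -> np.ndarray:
    """Draw MVN(0, h2 * sigma^2 * Phi_i) per family; columns are replicates.

    Returns shape (n,) when ``size`` is None, else (n, size).
    """
    cols = 1 if size is None else size
    out = np.zeros((phi.n_samples, cols))
    if h2 > 0:
        offset = 0
        for blk in phi.blocks:
            try:
                L = np.linalg.cholesky(blk)
            except np.linalg.LinAlgError:  # PSD but singular block
                w, V = np.linalg.eigh(blk)
                L = V * np.sqrt(np.clip(w, 0.0, None))
            z = rng.standard_normal((blk.shape[0], cols))
            out[offset : offset + blk.shape[0]] = L @ z
            offset += blk.shape[0]
        out *= np.sqrt(h2) * sigma_total
    return out[:, 0] if size is None else out


def simulate_trait(
    geno: GenotypeMatrix,
    phi: KinshipBlocks,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Raw trait values plus generated covariates for one replicate.

    Ordering follows ``geno.sample_ids`` (which must match ``phi``).
    """
    n = geno.n_samples
    y = np.full(n, config.intercept, dtype=float)
    covar = pd.DataFrame(index=geno.sample_ids)
    if config.with_covariates:
        covar = draw_covariates(n, rng)
        covar.index = geno.sample_ids
        for name, eff in config.covariate_effects.items():
            y += eff * covar[name].to_numpy()
    if config.causal_indices:
        idx = np.asarray(config.causal_indices, dtype=int)
        y += geno.dosages[:, idx] @ np.asarray(config.beta, dtype=float)
    y += polygenic_effects(phi, config.h2_polygenic, config.sigma_total, rng)
    y += rng.normal(
        0.0, np.sqrt(1.0 - config.h2_polygenic) * config.sigma_total, size=n
    )
    return y, covar


@dataclass
class Study:
    """One simulated study: families, genotypes, phenotype table, kinship."""

    pedigrees: list[Pedigree]
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable  # covariates + "trait" column
    phi: KinshipBlocks
    maf: np.ndarray


def simulate_study(config: SimulationConfig, seed: int) -> Study:
    """Generate a full study from one seed (structure, genotypes, trait)."""
    rng = np.random.default_rng(seed)
    peds = study_pedigrees(config)
    phi = phi_blocks(peds)
    maf = draw_mafs(config, rng)
    geno = drop_study_genotypes(peds, maf, rng)
    y, covar = simulate_trait(geno, phi, config, rng)
    pheno = covar.copy()
    pheno["trait"] = y
    pheno.index = geno.sample_ids
    pheno.index.name = "individual_id"
    return Study(peds, geno, PhenotypeTable(pheno), phi, maf)


def probands(study: Study) -> list[str]:
    """Designated proband per family: the first non-founder in pedigree order."""
    return [ped.nonfounders[0].individual_id for ped in study.pedigrees]


def ascertain_pedigrees(
    study: Study,
    rule: str,
    rng: np.random.Generator,
    keep_fraction: float = 1.0,
    quantile: float = 0.9,
) -> Study:
    """Retain a subset of families by an ascertainment rule.

    ``rule="random"`` keeps a uniform subset of ``keep_fraction`` of the
    families; ``rule="proband_extreme"`` keeps families whose proband's raw
    trait exceeds the given quantile of the study trait distribution (the
    operational stand-in for the population distribution).
    """
    trait = study.phenotypes.data["trait"]
    if rule == "random":
        n_keep = max(1, int(round(keep_fraction * len(study.pedigrees))))
        chosen = sorted(
            rng.choice(len(study.pedigrees), size=n_keep, replace=False).tolist()
        )
        keep = [study.pedigrees[k] for k in chosen]
    elif rule == "proband_extreme":
        threshold = float(np.quantile(trait.to_numpy(), quantile))
        keep = [
            ped
            for ped in study.pedigrees
            if float(trait.loc[ped.nonfounders[0].individual_id]) > threshold
        ]
    else:
        raise SimulationError(f"unknown ascertainment rule {rule!r}")
    if not keep:
        raise AscertainmentError(f"no pedigree satisfies rule {rule!r}")
    ids = [iid for ped in keep for iid in ped.ids]
    return Study(
        keep,
        study.genotypes.subset_samples(ids),
        study.phenotypes.subset_samples(ids),
        study.phi.subset(ids),
        study.maf,
    )


def write_study(study: Study, prefix: str) -> dict[str, str]:
    """Write the FAM + genotype-TSV + phenotype-TSV triple that dataio reads."""
    paths = {
        "fam": f"{prefix}.fam",
        "geno": f"{prefix}.geno.tsv",
        "pheno": f"{prefix}.pheno.tsv",
    }
    with open(paths["fam"], "w") as fh:
        for ped in study.pedigrees:
            for m in ped.members:
                sex = {"male": "1", "female": "2"}.get(m.sex, "0")
                fh.write(
                    f"{m.family_id}\t{m.individual_id}\t{m.father_id or 0}\t"
                    f"{m.mother_id or 0}\t{sex}\n"
                )
    gdf = pd.DataFrame(
        study.genotypes.dosages.astype(int),
        index=pd.Index(study.genotypes.sample_ids, name="individual_id"),
        columns=study.genotypes.variant_meta["id"],
    )
    gdf.to_csv(paths["geno"], sep="\t")
    study.phenotypes.data.to_csv(paths["pheno"], sep="\t", na_rep="NA")
    return paths
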