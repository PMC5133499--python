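"""Empirical type-I-error and power estimation over replicated analyses.

The calibration protocol mirrors a workshop-style family study: genotype
blocks are fixed (as real sequence data would be) while the phenotype is
re-simulated per replicate under the null; each replicate x block pair
contributes one p-value, and rejection rates are computed over the pooled
p-values at each nominal level.  Covariate adjustment is refit per
replicate.

The heavy lifting is shared with :mod:`owscore.score`: the genotype
covariance, moment fit, and kinship quadratic form are computed once per
block / per replicate and reused, since they do not depend on the other
axis.  A unit test pins the vectorized many-replicate path to
:func:`owscore.score.ow_score_statistic` on single replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .errors import MonomorphicRegionError, SimulationError
from .pedigree import phi_blocks
from .pvalue import moment_match_scaled_chisq
from .score import estimate_genotype_covariance, madsen_browning_weights
from .simulate import (
    SimulationConfig,
    draw_covariates,
    draw_mafs,
    drop_study_genotypes,
    polygenic_effects,
    simulate_study,
    study_pedigrees,
)
from .phenotype import TraitVector, adjust_covariates

logger = logging.getLogger(__name__)

DEFAULT_ALPHAS = (0.05, 0.01, 0.001)


@dataclass
class RejectionReport:
    """Rejection rates at nominal levels with binomial Monte-Carlo SEs."""

    alpha_levels: tuple[float, ...]
    rejection_rates: np.ndarray
    n_tests: int
    mc_standard_errors: np.ndarray
    p_values: np.ndarray | None = None

    def to_rows(self):
        return [
            {"alpha": a, "rejection_rate": float(r), "mc_se": float(s),
             "n_tests": self.n_tests}
            for a, r, s in zip(
                self.alpha_levels, self.rejection_rates, self.mc_standard_errors
            )
        ]


def empirical_rejection_rate(p_values, alpha_levels) -> RejectionReport:
    """Fraction of p-values at or below each nominal level.

    The Monte-Carlo standard error per level is sqrt(alpha(1-alpha)/n),
    i.e. the binomial SE at the *nominal* rate, matching how calibration
    bands are usually drawn.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    alphas = tuple(float(a) for a in np.atleast_1d(alpha_levels))
    if not alphas:
        raise ValueError("need at least one alpha level")
    rates = np.array([np.mean(p <= a) for a in alphas])
    ses = np.array([np.sqrt(a * (1.0 - a) / p.size) for a in alphas])
    return RejectionReport(alphas, rates, int(p.size), ses, p_values=p)


def _residual_traits(
    peds, phi, config: SimulationConfig, n_replicates: int, rng
) -> tuple[np.ndarray, np.ndarray]:
    """Null phenotype replicates, covariate-adjusted and centered.

    Covariates are drawn once (fixed per individual, as in real data); the
    polygenic and environmental components are redrawn per replicate.
    Returns the residual matrix (n x R) and per-replicate kinship quadratic
    forms computed on the residuals.
    """
    n = phi.n_samples
    y0 = np.full(n, config.intercept)
    X = None
    if config.with_covariates:
        covar = draw_covariates(n, rng)
        X = covar.to_numpy()
        for k, name in enumerate(covar.columns):
            y0 = y0 + config.covariate_effects.get(name, 0.0) * X[:, k]
    Y = y0[:, None] + polygenic_effects(
        phi, config.h2_polygenic, config.sigma_total, rng, size=n_replicates
    )
    Y = Y + rng.normal(
        0.0,
        np.sqrt(1.0 - config.h2_polygenic) * config.sigma_total,
        size=(n, n_replicates),
    )
    # Per-replicate least-squares adjustment via the (fixed) hat projector.
    design = np.ones((n, 1)) if X is None else np.column_stack([np.ones(n), X])
    Q, _ = np.linalg.qr(design)
    R = Y - Q @ (Q.T @ Y)
    R = R - R.mean(axis=0)  # exact centering
    quad = np.zeros(n_replicates)
    offset = 0
    for blk in phi.blocks:
        Rb = R[offset : offset + blk.shape[0]]
        quad += np.einsum("ir,ij,jr->r", Rb, blk, Rb)
        offset += blk.shape[0]
    return R, quad


def _ow_pvalues_many(G: np.ndarray, R: np.ndarray, quad: np.ndarray) -> np.ndarray:
    """OW-score p-values for one genotype block against many trait replicates."""
    cov = estimate_genotype_covariance(G)
    fit = moment_match_scaled_chisq(cov)
    Gk = G[:, cov.kept_variants]
    Gc = Gk - Gk.mean(axis=0)
    U = Gc.T @ R  # (M_kept, R); columns of R are centered
    T = np.sum(U * U / cov.sigma0_hat[:, None], axis=0) / quad
    return chi2.sf(T / fit.delta, fit.df)


def _ws_pvalues_many(G: np.ndarray, R: np.ndarray, quad: np.ndarray) -> np.ndarray:
    """Madsen-Browning-weighted score p-values against many trait replicates."""
    from .dataio import GenotypeMatrix
    import pandas as pd

    cov = estimate_genotype_covariance(G)
    geno = GenotypeMatrix(
        G,
        pd.DataFrame(
            {"id": [str(m) for m in range(G.shape[1])], "chrom": ".",
             "pos": np.arange(1, G.shape[1] + 1), "coded_allele": "A"}
        ),
        [str(i) for i in range(G.shape[0])],
    )
    w = madsen_browning_weights(geno).weights[cov.kept_variants]
    Gk = G[:, cov.kept_variants]
    x = Gk @ w
    xc = x - x.mean()
    U = xc @ R
    V = float(w @ cov.sigma_hat @ w) * quad
    return chi2.sf(U * U / V, 1)


def run_calibration_study(
    config: SimulationConfig,
    n_replicates: int = 200,
    n_blocks: int = 50,
    tests=("ow",),
    alpha_levels=DEFAULT_ALPHAS,
    seed: int = 0,
    kinship: str = "pedigree",
) -> dict[str, RejectionReport]:
    """Null rejection rates over replicate-by-block tests.

    Requires a null config (no causal effects).  ``kinship="identity"``
    deliberately ignores relatedness in the test denominator (Phi = I), a
    misspecification probe that should inflate type I error whenever the
    trait is family-correlated.
    """
    if config.causal_indices:
        raise SimulationError("calibration requires a null config (no causal beta)")
    if kinship not in ("pedigree", "identity"):
        raise ValueError("kinship must be 'pedigree' or 'identity'")
    ss = np.random.SeedSequence(seed)
    pheno_rng, geno_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    peds = study_pedigrees(config)
    phi = phi_blocks(peds)
    R, quad = _residual_traits(peds, phi, config, n_replicates, pheno_rng)
    if kinship == "identity":
        quad = np.einsum("ir,ir->r", R, R)

    collected: dict[str, list[np.ndarray]] = {t: [] for t in tests}
    for b in range(n_blocks):
        maf = draw_mafs(config, geno_rng)
        G = drop_study_genotypes(peds, maf, geno_rng).dosages
        try:
            if "ow" in collected:
                collected["ow"].append(_ow_pvalues_many(G, R, quad))
            if "ws" in collected:
                collected["ws"].append(_ws_pvalues_many(G, R, quad))
        except MonomorphicRegionError:  # pragma: no cover - vanishing probability
            logger.warning("block %d entirely monomorphic; skipped", b)
    return {
        t: empirical_rejection_rate(np.concatenate(ps), alpha_levels)
        for t, ps in collected.items()
    }


def run_power_study(
    config: SimulationConfig,
    n_replicates: int = 200,
    tests=("ow", "ws"),
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, RejectionReport]:
    """Rejection rate under an alternative (power) per test.

    Each replicate simulates a fresh study (genotypes and trait), adjusts
    covariates, and tests the region with each requested method at the given
    level.
    """
    from .score import ow_score_statistic, weighted_score_statistic

    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_replicates)]
    pvals: dict[str, list[float]] = {t: [] for t in tests}
    for s in seeds:
        study = simulate_study(config, s)
        raw = study.phenotypes.data
        trait = TraitVector(raw["trait"].to_numpy(), list(raw.index))
        covars = raw.drop(columns=["trait"])
        adj = adjust_covariates(trait, covars if covars.shape[1] else None)
        if "ow" in pvals:
            pvals["ow"].append(
                ow_score_statistic(study.genotypes, adj, study.phi).p_value
            )
        if "ws" in pvals:
            w = madsen_browning_weights(study.genotypes)
            pvals["ws"].append(
                weighted_score_statistic(study.genotypes, adj, study.phi, w).p_value
            )
    return {t: empirical_rejection_rate(np.array(p), (alpha,)) for t, p in pvals.items()}


def write_report(reports: dict[str, RejectionReport], path, header_lines=()) -> None:
    """Write rejection reports as TSV with '#'-prefixed metadata lines."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("test\talpha\trejection_rate\tmc_se\tn_tests\n")
        for name, rep in reports.items():
            for row in rep.to_rows():
                fh.write(
                    f"{name}\t{row['alpha']:g}\t{row['rejection_rate']:.15g}\t"
                    f"{row['mc_se']:.15g}\t{row['n_tests']}\n"
                )
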