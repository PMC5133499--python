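"""Retrospective score statistics for rare-variant association in pedigrees.

The tests here treat traits as fixed and genotypes as random (a retrospective
view), which makes them valid under phenotype-based ascertainment of
families.  For a region of M variants with weighted burden
x_ij = sum_m w_m g_ijm, the weighted score statistic is

    T_score = U^2 / V,
    U = sum_ij (x_ij - xbar)(y_ij - ybar),
    V = (w' Sigma w) * sum_i y_i' Phi_i y_i,

with Sigma the per-individual genotype covariance (estimated with divisor
N = total sample size) and Phi_i twice the kinship matrix of family i.
Replacing Sigma by its diagonal Sigma0 — rare variants are essentially
uncorrelated — gives T0(w), whose maximum over weights is attained at
w = Sigma0^{-1} u.  That maximum is the optimally weighted (OW) score
statistic:

    T_OW = u' Sigma0^{-1} u / sum_i y_i' Phi_i y_i
         = sum_m (u_m^2 / sigma_mm) / sum_i y_i' Phi_i y_i,

whose null distribution is approximated by a moment-matched scaled
chi-square (module :mod:`owscore.pvalue`).

The trait entering both U and the quadratic form is the centered,
covariate-adjusted trait: the null moments of u require mean-zero values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .dataio import GenotypeMatrix
from .errors import DegenerateTraitError, DegenerateWeightsError, MonomorphicRegionError
from .pedigree import KinshipBlocks
from .phenotype import TraitVector
from .pvalue import (
    ScaledChiSquareFit,
    mixture_chisq_pvalue,
    moment_match_scaled_chisq,
    scaled_chisq_pvalue,
)

logger = logging.getLogger(__name__)


@dataclass
class GenotypeCovariance:
    """Genotype covariance Sigma-hat over the kept (polymorphic) variants.

    ``sigma_hat`` is the M_kept x M_kept covariance with divisor N;
    ``sigma0_hat`` is its diagonal as a vector.  Monomorphic variants are
    recorded in ``dropped_variants`` and excluded from every downstream
    quantity (they contribute 0/0 otherwise).
    """

    sigma_hat: np.ndarray
    sigma0_hat: np.ndarray
    kept_variants: np.ndarray  # original column indices
    dropped_variants: np.ndarray


@dataclass
class WeightVector:
    """Per-variant weights w (dimensionless); nonnegative for fixed-weight tests."""

    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float).ravel()


@dataclass
class TestResult:
    """Outcome of one region test.

    ``per_variant_u`` holds the score contributions u_m for the kept
    variants; ``quad_form_y`` is the kinship quadratic form
    sum_i y_i' Phi_i y_i shared by every weighting of the same data.
    """

    statistic: float
    scale_delta: float
    df_d: float
    p_value: float
    per_variant_u: np.ndarray
    quad_form_y: float
    n_variants_used: int
    method: str = "ow-score"


def estimate_genotype_covariance(geno: GenotypeMatrix | np.ndarray) -> GenotypeCovariance:
    """Estimate Sigma by the pooled outer-product formula with divisor N.

    Sigma-hat = (1/N) sum_ij (g_ij - gbar)(g_ij - gbar)', with gbar the grand
    mean dosage vector over all analyzed individuals.  Variants with zero
    variance are moved to ``dropped_variants`` (warning); if every variant is
    monomorphic a :class:`MonomorphicRegionError` is raised.
    """
    G = geno.dosages if isinstance(geno, GenotypeMatrix) else np.asarray(geno, float)
    if G.shape[0] < 2:
        raise ValueError("need at least 2 analyzed individuals")
    Gc = G - G.mean(axis=0)
    var = np.einsum("ij,ij->j", Gc, Gc) / G.shape[0]
    kept = np.flatnonzero(var > 0)
    dropped = np.flatnonzero(var == 0)
    if kept.size == 0:
        raise MonomorphicRegionError(
            "all variants are monomorphic in the analyzed sample"
        )
    if dropped.size:
        logger.warning("dropping %d monomorphic variant(s)", dropped.size)
    Gk = Gc[:, kept]
    sigma = (Gk.T @ Gk) / G.shape[0]
    return GenotypeCovariance(sigma, np.diag(sigma).copy(), kept, dropped)


def trait_quadratic_form(trait: TraitVector, phi: KinshipBlocks) -> float:
    """Blockwise kinship quadratic form sum_i y_i' Phi_i y_i on centered values.

    Requires the trait to be centered (``grand_mean_removed``) and the block
    member order to match the trait order.  A zero result (constant trait)
    raises :class:`DegenerateTraitError`.
    """
    if not trait.grand_mean_removed:
        raise ValueError("trait must be centered (grand_mean_removed) first")
    if phi.sample_ids != list(trait.sample_ids):
        raise ValueError("kinship block order does not match the trait order")
    y = trait.values
    total = 0.0
    offset = 0
    for blk in phi.blocks:
        yi = y[offset : offset + blk.shape[0]]
        total += float(yi @ blk @ yi)
        offset += blk.shape[0]
    if total <= 0.0:
        raise DegenerateTraitError(
            "kinship quadratic form is zero: trait is constant after centering"
        )
    return total


def madsen_browning_weights(geno: GenotypeMatrix) -> WeightVector:
    """Allele-frequency weights w_m = 1 / sqrt(N q_m (1 - q_m)).

    q_m is estimated from the full analyzed sample with a +1/+2 pseudocount,
    q_m = (sum_ij g_ijm + 1) / (2N + 2), which keeps the weight finite even
    for variants unobserved in the sample.  Rarer variants receive strictly
    larger weights.
    """
    G = geno.dosages
    N = G.shape[0]
    q = (G.sum(axis=0) + 1.0) / (2.0 * N + 2.0)
    return WeightVector(1.0 / np.sqrt(N * q * (1.0 - q)))


def weighted_score_statistic(
    geno: GenotypeMatrix,
    trait: TraitVector,
    phi: KinshipBlocks,
    weights: WeightVector,
    covariance_mode: str = "full",
    cov: GenotypeCovariance | None = None,
    quad_form: float | None = None,
) -> TestResult:
    """Burden-style score test T_score = U^2 / V for a fixed weight vector.

    ``covariance_mode`` selects V's genotype term: ``"full"`` uses
    w' Sigma-hat w; ``"diagonal"`` uses w' Sigma0-hat w (the T0(w) form).
    The statistic is chi2_1 distributed under the null (delta = 1, d = 1).
    Monomorphic variants contribute nothing to U and are excluded from the
    covariance, so weights are subset to the kept variants.

    ``cov`` and ``quad_form`` may be supplied to reuse expensive pieces
    across many traits on the same genotypes.
    """
    if covariance_mode not in ("full", "diagonal"):
        raise ValueError("covariance_mode must be 'full' or 'diagonal'")
    w = weights.weights
    if w.size != geno.n_variants:
        raise ValueError("weights length must equal the variant count")
    if cov is None:
        cov = estimate_genotype_covariance(geno)
    if quad_form is None:
        quad_form = trait_quadratic_form(trait, phi)
    wk = w[cov.kept_variants]

    G = geno.dosages[:, cov.kept_variants]
    x = G @ wk
    y = trait.centered()
    U = float((x - x.mean()) @ y)
    gw = float(wk @ cov.sigma_hat @ wk) if covariance_mode == "full" else float(
        wk @ (cov.sigma0_hat * wk)
    )
    V = gw * quad_form
    if V <= 0.0:
        raise DegenerateWeightsError("V = 0: weighted burden has zero variance")
    T = U * U / V
    return TestResult(
        statistic=T,
        scale_delta=1.0,
        df_d=1.0,
        p_value=float(chi2.sf(T, 1)),
        per_variant_u=(G - G.mean(axis=0)).T @ y,
        quad_form_y=quad_form,
        n_variants_used=int(cov.kept_variants.size),
        method="ws-score" if covariance_mode == "full" else "t0",
    )


def ow_score_statistic(
    geno: GenotypeMatrix,
    trait: TraitVector,
    phi: KinshipBlocks,
    cov: GenotypeCovariance | None = None,
    quad_form: float | None = None,
    fit: ScaledChiSquareFit | None = None,
    pvalue_method: str = "scaled-chisq",
) -> TestResult:
    """Optimally weighted score test T_OW = sum_m (u_m^2/sigma_mm) / quad_form.

    u_m = sum_ij (g_ijm - gbar_m)(y_ij - ybar) over kept variants.  The
    statistic equals the maximum of T0(w) over all weight vectors, attained
    at w = Sigma0^{-1} u.  Its p-value comes from the moment-matched scaled
    chi-square by default, or from the exact eigenvalue mixture with
    ``pvalue_method="mixture"``.

    ``cov``, ``quad_form`` and ``fit`` may be precomputed and reused across
    traits sharing the same genotypes (they do not depend on the trait).
    """
    if pvalue_method not in ("scaled-chisq", "mixture"):
        raise ValueError("pvalue_method must be 'scaled-chisq' or 'mixture'")
    if cov is None:
        cov = estimate_genotype_covariance(geno)
    if quad_form is None:
        quad_form = trait_quadratic_form(trait, phi)
    if fit is None:
        fit = moment_match_scaled_chisq(cov)

    G = geno.dosages[:, cov.kept_variants]
    y = trait.centered()
    u = (G - G.mean(axis=0)).T @ y
    T = float(np.sum(u * u / cov.sigma0_hat) / quad_form)
    if pvalue_method == "mixture":
        p = mixture_chisq_pvalue(T, cov)
    else:
        p = scaled_chisq_pvalue(T, fit)
    return TestResult(
        statistic=T,
        scale_delta=fit.delta,
        df_d=fit.df,
        p_value=p,
        per_variant_u=u,
        quad_form_y=quad_form,
        n_variants_used=int(cov.kept_variants.size),
        method="ow-score",
    )
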