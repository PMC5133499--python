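# Methods

This note documents the statistical model implemented by `owscore`, the
synthetic study generator used to validate it, the numerical choices made
where the design was open, and the known limitations — in particular the
finite-sample behaviour of the scaled-χ² p-value, which the package's own
calibration harness quantifies.

## Model and statistics

Let the study comprise n pedigrees, pedigree i having n_i members with
trait values y_ij and genotype dosage vectors g_ij ∈ {0,1,2}^M for a region
of M variants. Conditional on genotypes the working trait model is
y_ij ~ N(a + x_ij β, σ²) with the weighted burden x_ij = Σ_m w_m g_ijm.
The score test of β = 0 is derived from the *retrospective* likelihood
Π_i Pr(g_i | y_i): traits are fixed, genotypes random. Ascertainment that
depends only on trait values then cancels from the likelihood, which is the
reason this family of tests remains valid for pedigrees collected through
extreme probands.

The score statistic and its variance are

- T_score = U²/V with U = Σ_ij (x_ij − x̄)(y_ij − ȳ),
- V = (wᵀ Σ̂ w) · Σ_i y_iᵀ Φ_i y_i,

where Φ_i = 2 × kinship matrix of pedigree i and Σ̂ is the pooled
genotype covariance estimated with divisor N = Σ_i n_i (not N − 1). The
kinship term prices in that relatives share genotypes: under Mendelian
transmission cov(g_jm, g_km) = Φ_jk σ_mm exactly, so
var(u_m | y) = σ_mm Σ_i y_iᵀ Φ_i y_i.

Treating rare variants as uncorrelated replaces Σ̂ by its diagonal Σ̂₀ in
the statistic, giving T₀(w); as a Rayleigh-quotient maximization, T₀ is
maximal at w = Σ̂₀⁻¹u, yielding the optimally weighted statistic
T_OW = Σ_m (u_m²/σ_mm) / Σ_i y_iᵀ Φ_i y_i. T_OW needs no weight choice and
is invariant to affine rescaling of the trait and to allele-coding flips
(u_m changes sign, σ_mm does not). For unrelated individuals and M = 1 it
reduces to N·r², the classical regression score test — a property used as a
test oracle. The full covariance Σ̂ is retained in the null moments (below),
so correlation among variants, where present, is accounted for in the
reference distribution rather than in the statistic.

Two fixed-weight comparators are kept behind the same interface: arbitrary
w with either the full (wᵀΣ̂w) or diagonal (wᵀΣ̂₀w) variance, referred to
χ²₁, and Madsen–Browning weights w_m = 1/√(N q̂_m(1 − q̂_m)). The allele
frequency q̂_m = (Σ_ij g_ijm + 1)/(2N + 2) is taken from the full analyzed
sample with a pseudocount; the original proposal used unaffected controls,
which do not exist for a quantitative trait.

### Null distribution

T_OW is asymptotically Σ_k λ_k χ²₁(k), with λ_k the eigenvalues of
Σ̂₀^{-1/2} Σ̂ Σ̂₀^{-1/2}. The default p-value uses a scaled χ², δ·χ²_d,
matched to the first two moments:

    μ̂_T = trace(Σ̂ Σ̂₀⁻¹),  σ̂²_T = 2 trace((Σ̂ Σ̂₀⁻¹)²),
    δ̂ = σ̂²_T / (2 μ̂_T),   d̂ = 2 μ̂_T² / σ̂²_T,

so that δ̂·d̂ = μ̂_T and 2δ̂²d̂ = σ̂²_T by construction. Tail probabilities
are computed on the log scale (reportable to ~1e−300). The exact mixture
p-value is available as a cross-check via Imhof-type numerical inversion of
the characteristic function (absolute accuracy 1e−9, eigenvalues below
1e−10 × λ_max truncated, closed form used when all positive eigenvalues are
equal — the diagonal and rank-1 cases, where the two routes agree exactly).
A separate Satterthwaite variant would duplicate the scaled-χ² moment match
and is not implemented.

### Trait preparation

Measurements repeated over time points are averaged per individual
(complete case); the average is regressed on the covariates by ordinary
least squares and the residuals — exactly mean-zero and orthogonal to the
design — are the analysis trait. The quadratic form Σ y_iᵀΦ_i y_i is
evaluated on these centered residuals: the null moments of u require
mean-zero y, and residual centering makes the defensive grand-mean
subtraction in the formulas a no-op. Adjustment deliberately ignores family
structure (no mixed model): relatedness is handled by the kinship term of
the test itself, and the two-stage procedure keeps the null fit free of
variance components. Residuals are not re-scaled to unit variance — the
statistic is scale-invariant, so it would change nothing.

### Kinship

Kinship coefficients are computed by the standard founders-first recursion
(φ(c,b) = (φ(p,b)+φ(q,b))/2, φ(c,c) = 1/2 + φ(p,q)/2), which handles
inbreeding loops arising within the recorded pedigree. Founders are assumed
mutually unrelated and non-inbred; the model is autosomal (the sex field is
carried but unused). Individuals referenced as parents without their own
record are inserted as founders with a warning, matching common FAM-file
practice. Analysis restricted to complete cases subsets rows/columns of the
full-pedigree Φ_i, so relationships mediated by excluded members remain
correct. The recursion is validated against a gene-dropping IBD oracle
(200,000 allele drops through a three-generation pedigree, agreement within
3 Monte-Carlo SE for every pair).

## Synthetic study generator

The generator emulates a workshop-scale family sequencing study and is the
substrate for all calibration and power claims:

| parameter | default | meaning |
|---|---|---|
| n_pedigrees | 20 | families per study |
| sibships | (3, 3, 2) | children per couple per generation; with married-in founder spouses this gives 44 members / 4 generations per family, 880 in total |
| n_variants | 100 | variants per region/block |
| MAF | U(0.001, 0.05) | per-variant founder minor-allele frequency |
| h2_polygenic | 0.3 | share of trait variance from the kinship-structured polygenic term |
| sigma_total | 1.0 | trait SD (polygenic + environmental) |
| covariates | sex (Bernoulli 0.5, effect 0.5), age (N(50, 10²), 0.02/yr), medication (Bernoulli 0.3, 0.3), smoking (Bernoulli 0.25, 0.4) | drawn once per study, regressed out before testing |

Founder genotypes are two independent allele draws per variant
(Hardy–Weinberg); descendants receive one allele from each parent,
uniformly per meiosis per variant (gene dropping), which reproduces
cov(g_j, g_k) = Φ_jk σ_m exactly. The trait is
y = a + Σ β_m g_m + covariate effects + p + e with p ~ MVN(0, h²σ²Φ_i) per
family and e ~ N(0, (1−h²)σ²); genetic variance from β is additional to σ²
rather than carved out of it (power is monotone in β either way). With
h² = 0 the generator reduces to the plain normal-given-genotype model.
Variants are mutually independent given the founder frequencies: there is
**no linkage disequilibrium**, no haplotype structure, and no site-frequency
spectrum beyond the uniform MAF law — deliberate simplifications whose
consequences for calibration are discussed below. Extreme-proband
ascertainment (keep families whose proband, the first non-founder, exceeds
a trait quantile) is provided to exercise the enrichment argument; the
default study is randomly ascertained. All randomness flows from explicit
seeds; identical config + seed is bitwise reproducible.

## Evaluation protocol and problem sizes

Calibration mirrors a replicated-phenotype design: genotype blocks are
generated once and held fixed (as real sequence data would be), the null
phenotype is re-simulated per replicate, covariate adjustment is refit per
replicate, and each replicate × block pair contributes one p-value. The
default run is 200 replicates × 50 blocks = 10,000 p-values, sized so the
binomial SE at α = 0.001 (0.00032) resolves the third decimal while the
whole study runs in seconds; the per-block covariance fit and per-replicate
quadratic forms are computed once and shared, and a unit test pins this
fast path to the single-test reference implementation. Power runs simulate
fresh genotypes and traits per replicate. No multiple-testing adjustment is
applied anywhere; rates are raw per-region rejection proportions.

## Finite-sample behaviour of the scaled-χ² p-value

On the default preset the calibration harness shows the OW-score test is
**valid but conservative**: empirical type I error ≈ 0.027 / 0.0034 /
0.0005 at nominal 0.05 / 0.01 / 0.001 (10,000 null tests, seed 1). The
package's own diagnostics attribute this to two finite-sample effects,
both reproducible with the shipped tools:

1. **Noise in the variance estimate.** σ̂²_T evaluates
   2·trace((Σ̂Σ̂₀⁻¹)²) at the *estimated* covariance. Its off-diagonal
   entries are pure sampling noise when variants are independent, yet they
   enter the trace quadratically, adding ≈ M(M−1)·trace(Φ²)/N² (about +24
   on a true value of ≈ M ≈ 97 at N = 880, trace(Φ²) ≈ 2100). The fitted
   scale δ̂ ≈ 1.23 therefore overstates the true null spread — the measured
   variance of T across 20,000 null replicates is ≈ 2M — and the tail
   threshold lands too far right. The effect grows with M²/N and with
   family structure (through trace(Φ²)), and *shrinks* when true
   correlation between variants dominates the trace, as it would for real
   sequence data with linkage disequilibrium; the LD-free generator is the
   worst case for this estimator.
2. **Few-copy variants under family-correlated traits.** For a variant
   whose minor allele appears only a handful of times, the realized σ̂_mm
   is strongly correlated with u_m², and dividing by it strips the
   between-replicate frequency variation that the kinship term prices in;
   per-variant score contributions then average slightly below 1 (≈ 0.95
   at MAF ≤ 0.005, h² = 0.3), lowering the statistic's mean a few percent
   below μ̂_T.

Neither effect threatens validity (rejection never exceeds nominal), and
the misspecification probe shows the kinship denominator is load-bearing:
replacing Φ by the identity on the same family-correlated null data drives
the α = 0.05 rejection rate far above nominal. Users testing regions with
many variants and no appreciable LD should expect the scaled-χ² p-values to
be conservative at roughly the factor above; the mixture p-value inherits
the same estimated spectrum and is not a remedy.

## Numerical choices and degenerate inputs

- Monomorphic variants are excluded from u, Σ̂, Σ̂₀ (`n_variants_used`
  records the effective M); a fully monomorphic region is a named error.
- A constant (degenerate) trait, V = 0 weights, empty sample intersections,
  rank-deficient covariate designs (offending columns named), parent
  cycles, single-parent records, and duplicate IDs are all distinct errors.
- Topological ordering uses founder-stripping with a heap keyed by input
  position: ties break by input order and already-sorted input is preserved.
- Dosages are recoded to minor-allele counts at load time (flip g → 2 − g
  when the coded allele's frequency exceeds 0.5; exact 0.5 left as coded);
  the statistic is invariant to this, so it is cosmetic but keeps reported
  frequencies interpretable. Multi-allelic VCF records are skipped with a
  warning. Coordinates are 1-based inclusive throughout.
- Genomic-region filtering applies to positional (VCF) input; TSV dosage
  matrices carry no positions, so region requests on them raise and a
  variant-ID filter is offered instead. No MAF ceiling is applied by
  default; `--max-maf` exists.
- Complete-case analysis only: individuals with any missing genotype,
  trait, or covariate among the analysis columns are dropped before
  alignment.

## Limitations

- The generator does not model LD, realistic site-frequency spectra,
  de novo variation, or genotyping error; passing calibration here shows
  correctness of the bookkeeping under the stated model, not robustness to
  real-sequence artifacts (and, per the conservatism analysis above, the
  LD-free null is actually the hard case for the moment-matched p-value).
- Qualitative traits and longitudinal (per-time-point) modeling are out of
  scope; repeated measures are averaged.
- Kinship is pedigree-based only — no genotype-based relatedness
  estimation, no X/mitochondrial models.
- Variance-component kernel tests with a fitted mixed-model null (the
  famSKAT family) are a different method and are not provided.
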