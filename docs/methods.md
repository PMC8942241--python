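# Methods

## Model

A single tested locus in a mapping population is described by the linear
mixed model

    y = Xβ + zα + ξ + ε,    ξ ~ N(0, A σξ²),  ε ~ N(0, I σ²),

with `y` the trait vector (length n), `X` the fixed design (intercept plus
covariates such as sex), `z` the genotype indicator of the locus, `ξ` a
polygenic effect with additive relationship (numerator) matrix `A`, and
homogeneous independent residuals (the residual structure is fixed to the
identity; no other structure is supported). Genotypes at a biallelic locus
are coded +1 (A1A1), 0 (A1A2), −1 (A2A2) and standardized to sample mean 0
and sample variance 1 before fitting, so the variance contributed by the
locus is σα² = α². Under Hardy–Weinberg equilibrium the raw code has mean
p − q and variance 2pq; that assumption enters only the closed-form genotype
moments, never the estimators, which operate on observed codes.

### Standardization denominator

The (n−1)-denominator sample standard deviation is used, so the standardized
code has sum of squares n − 1 and the single-marker regression satisfies
s_α̂² = σ̂²/(n−1). This choice makes the corrected heritability *exactly*
equal to the adjusted R² of the single-marker regression (`r2_family`
asserts the identity at 1e−12) and is therefore not a free parameter.
Missing codes are mean-imputed with a logged warning before standardization.

### Kinship

Marker-inferred kinship is the cross-product of the column-standardized
marker matrix rescaled so that tr(K) = n (monomorphic columns are dropped
with a warning). The full-sib numerator matrix is block-diagonal with 1 on
the diagonal and the full-sib additive relationship 1/2 within families; its
eigenvalues are the compound-symmetry pair {1/2, 1 + (m−1)/2}. With
m_sibs = 1 the matrix equals the identity and the polygenic and residual
variances are confounded; the fitter detects a covariance proportional to
the identity and raises rather than returning an arbitrary split.

## Estimation

### Fixed-model (moment) route

With `z` inside the fixed design, REML estimates (σξ², σ²) by maximizing the
restricted log-likelihood

    L(θ) = −½[(n−p) ln 2π + ln|V| + ln|XᵀV⁻¹X| + rᵀV⁻¹r],   V = Aσξ² + Iσ²,

with r the GLS residual. The Gaussian constant is included so values match
standard mixed-model software (verified against lme4 on a compound-symmetry
fixture). The residual variance is profiled out analytically and the single
variance ratio λ = σξ²/σ² is maximized on the log scale — a spectral
decomposition of `A` makes each evaluation O(n) after an O(n³) setup — by a
41-point coarse grid over log λ ∈ [−25, 25] followed by bounded Brent
refinement (xatol 1e−11), with an exact comparison against the λ = 0
boundary (ordinary least squares) so that zero components are reported as
exact zeros. Without a kinship matrix the fit is the closed-form OLS limit.

The moment estimate of the QTL variance is σ̂α² = α̂² − s_α̂², where s_α̂² is
the marker diagonal of (XᵀV̂⁻¹X)⁻¹. Since E[α̂²] = α² + s_α̂², the untruncated
form is unbiased; the truncated form max(·, 0) is the practical estimate.
The fixed model carries no sampling covariance for the moment estimate, so
no standard error is attached to its heritability.

### Random-model (REML) route

Treating α ~ N(0, σα²) moves the locus into the covariance,
V = zzᵀσα² + Aσξ² + Iσ². The two variance ratios are maximized by
Nelder-Mead on the log scale (restarted once from its own solution; xatol
1e−10, fatol 1e−13), warm-started from the fixed-model fit's implied ratios,
and compared against the exact boundary fits with either or both components
removed; boundary solutions are flagged. The asymptotic covariance of
θ̂ = (σ̂α², σ̂ξ², σ̂²) is the inverse *expected* (Fisher) information
I_ij = ½ tr(P V_i P V_j) evaluated at θ̂ on the original variance scale;
published tables produced by software using observed information may differ
by a few percent (a finite-difference Hessian agrees within 5% on test
fixtures). When the inverse information yields a negative diagonal entry at
a boundary solution, the affected rows/columns are reported as NaN rather
than zero.

### Moment/REML equivalence — exact and approximate forms

At an interior REML optimum the score equation for σα² gives exactly

    σ̂α² = α̂_gls² − s_gls²,

where α̂_gls and s_gls are the GLS effect and standard error computed at the
*random model's* nuisance components (exposed as `alpha_gls_` /
`s_alpha_gls_` and tested at 1e−4). When each model estimates its own
nuisance components, the two routes differ at O(1/n): without a polygene the
models share the profile exactly (the identity holds to optimizer precision,
~1e−6 at n = 50); with a polygene the discrepancy is ~1e−2 at n = 50 and
~2e−4 at n ≈ 280 — at the scale of published scatter plots and 4-decimal
tables the two appear identical. This is why the equivalence property is
asserted exactly for the single-marker design but only approximately for
the polygenic design.

### Heritability and its standard error

ĥ² = σ̂α²/(σ̂α² + σ̂ξ² + σ̂²), with the QTL variance clipped at zero. The
delta-method variance uses the contrasts L_X = (1,0,0) and L_Y = (1,1,1):

    var(ĥ²) ≈ (var(X)Y² − 2cov(X,Y)XY + var(Y)X²)/Y⁴,

implemented in the numerically stable polynomial form (no 0/0 at X = 0) and
validated against complex-step gradient propagation at 1e−10. The same
function serves the two-component (no polygene) model.

Auxiliary measures: pseudo-R² = 1 − exp(−LRT/n); the single-marker R²,
adjusted R² and corrected heritability family (adjusted R² ≡ corrected h²,
and R² strictly exceeds it whenever σ̂² > 0); the k-level randomized-fixed-
model estimator (1/k)[Σα̂ₖ² − tr var(α̂)] for grouped effects such as the four
epistatic levels of a locus pair; and the LD partition of multi-locus
variance, where under the fixed treatment locus k contributes
σ_Zk²αₖ² + Σ_{k′≠k} σ_ZkZk′ αₖαₖ′ (cross terms may be negative under
antagonistic LD and are reported as-is), while under the random treatment
each standardized locus contributes αₖ² regardless of LD.

## Genome scans

Interval mapping fits each position without a polygenic term; polygenic
mapping includes the whole-genome kinship at every position (no
leave-one-chromosome-out re-estimation). Under the random locus treatment
the Wald test is still taken from the companion fixed fit. Pseudo markers
are inserted on a per-interval cM grid as the conditional expectation of the
F2 code given the flanking genotypes, with genotype transition probabilities
from independently recombining gametes under the Haldane map (Haley–Knott
style regression on expected codes; the imputation is isolated in
`expected_f2_code` so an alternative can be swapped in). Pseudo markers are
tested but excluded from the Bonferroni denominator: the Wald threshold is
the χ²(1) quantile at 1 − α/(number of real markers). P-values are χ²(1)
upper tails with no genomic control. Per-marker failures (e.g. monomorphic
columns) are flagged and skipped, never fatal. Sex covariates follow the
1 = male, 0 = female coding.

## Simulation designs

The generator defaults are the study conditions themselves:

- **F2 single marker** — genotypes segregate 1:2:1, codes standardized per
  replicate with sample moments, y = μ + zα + ε with μ = 10, σ² = 20, and
  α² = h²/(1−h²)·σ². No polygene; this is the interval-mapping setting.
- **Full-sib polygenic** — families of m full sibs (default 10 × 5 = 50),
  compound-symmetry numerator matrix, polygenic value = family effect +
  individual deviation each with variance σξ²/2, μ = 0 (our default; the
  mean is immaterial to variance estimation), σξ² = σ² = 10, and
  α² = h²/(1−h²)·(σξ² + σ²), giving the grid α² ∈ {1.0526, 2.2222, 3.5294,
  5.0000} at h² ∈ {0.05, 0.10, 0.15, 0.20}.

One seeded generator drives each experiment, with the grid index and
replicate index folded into the stream, so runs are reproducible to the
last bit for genotypes and to 1e−12 for phenotypes. A replicate drawing a
monomorphic marker is redrawn (capped at 100 attempts; only relevant at
n < ~10). The full heritability grid 0–0.2 in 0.001 steps is exposed
(`full_heritability_grid`), but experiments default to a coarse grid — the
bias and equivalence properties are grid-dense, so the coarse grid tests the
same claims at a fraction of the cost. Replicated experiments aggregate by
first averaging the variance estimates and then converting the average to a
heritability.

What the generators deliberately omit: linkage between markers (scan panels
are unlinked), dominance, segregation distortion, missing genotypes,
selection/ascertainment (no Beavis-effect conditioning), and non-Gaussian
residuals. Passing tests therefore certify the estimator algebra and the
sampling behavior under the stated designs, not robustness to those
real-data features.

## Problem sizes and numerical choices

Test and acceptance runs use 100 replicates per heritability level for the
equivalence study (10 × 5 full-sib design) and 500 replicates at
n ∈ {25, 250}, h² ∈ {0.05, 0.15} for the bias study — enough for
3-Monte-Carlo-SE assertions while keeping a full suite run to a few
minutes. Three-component fits use direct Cholesky solves (intended for
n up to a few thousand); two-component fits reuse a single spectral
decomposition across likelihood evaluations and, where the same kinship is
shared across replicates, across fits. Collinearity of the marker with
covariates raises an error rather than silently dropping a column.

## Known limitations

- The delta-method SE is a first-order approximation; near boundaries
  (σ̂α² = 0) it is reported as NaN when the information matrix does not
  invert cleanly, and the usual caveats about asymptotic normality of
  variance components at small n apply.
- E[α̂²] = α² + s_α̂² treats s_α̂² as known; in practice it is estimated, and
  the second-order effect of that substitution is not modeled.
- The heritability of a truncated-to-zero QTL variance is reported as 0;
  only random-model fits carry a standard error.
- No VCF/PLINK ingestion, general pedigree recursion, dominance coding,
  multi-trait models, or permutation thresholds.
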