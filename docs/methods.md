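# Methods

## The model and the test

`sumshare` tests whether one SNP is pleiotropic — associated with at least
one of `q` binary phenotypes — using data that is physically split across
`K` sites and cannot be pooled at the individual level.  For each phenotype
`j` a marginal logistic model is assumed,

    logit P(Y_j = 1 | X) = alpha_j + beta_j X,

with `X in {0, 1, 2}` the additive genotype.  The `q` marginal likelihoods
are multiplied into a composite likelihood; their dependence is deliberately
left unmodelled.  The null hypothesis is `beta = (beta_1, ..., beta_q) = 0`.

The score of the composite log-likelihood at the null, with the intercepts
profiled out, has per-subject contributions

    u_ij = (x_i - xbar_{j,s_j(i)}) * (y_ij - p_{j,s_j(i)}),

where `p_{j,s}` is the pooled prevalence of phenotype `j` inside covariate
stratum `s` (so `expit(alpha_hat_j)` is exactly the stratum prevalence) and
`xbar_{j,s}` the pooled genotype mean in that stratum.  Because the
composite likelihood misstates the joint distribution, the test uses the
robust (empirical) variance of the score:

    S = sum_i u_i,    V = sum_i u_i u_i',    T = S V^{-1} S'.

Under the null `T ~ chi^2_q` asymptotically and `p = 1 - Psi_q(T)`.
Without covariates there is a single stratum and `S`, `V` collapse to
`S_j = sum_i x_i (y_ij - ybar_j)` and
`V_jl = sum_i (x_i - xbar)^2 (y_ij - ybar_j)(y_il - ybar_l)` — the genotype
centering in `S` is immaterial then, because the phenotype residuals sum to
zero over the pooled sample.  We use the centered form in code for both the
unadjusted and the stratified case, so the two paths are literally the same
computation and the single-stratum reduction is bit-for-bit.

### Distributed computation and losslessness

Every term of `S` and `V` is a sum over subjects, so the statistic
decomposes exactly over sites.  The protocol has two rounds:

1. each site shares per-stratum counts, phenotype sums and genotype sums
   (`n_{k,j,s}`, `sum y`, `sum x`); the analyst returns pooled means;
2. each site shares `S_k = sum_{i in k} u_i` and `V_k = sum_{i in k} u_i u_i'`;
   the analyst sums them and forms `T`.

The distributed and pooled statistics are mathematically identical; in
floating point they differ only by summation order.  All lossless
assertions therefore use a 1e-12 relative tolerance rather than equality.

### Covariate adjustment

Only categorical covariates are supported: the adjustment works by
centering within covariate-defined cells, which requires cell means —
quantities that pool exactly from per-cell counts and sums.  Continuous
covariates would require iterative fitting and break the one-round-per-stage
lossless property; discretize them first (as done for age here).  Strata
are opaque labels and may differ per phenotype, so each disease can be
adjusted for its own age-at-onset binning.  Whether the original derivation
centers the genotype at the pooled or the stratum mean is not documented
anywhere we could check; we center both genotype and phenotype at stratum
means, which keeps the no-covariate case an exact special case and keeps
`V` a Gram matrix (symmetric PSD by construction).

### Numerical choices

* `T` is computed with an LU solve of `V` rather than a Cholesky
  factorization: `V` is PSD by construction so the PD check buys nothing,
  LU keeps exact scalar divisions exact (the 1-phenotype worked example
  yields `T = 2.0` exactly), and an exactly singular `V` (duplicated
  phenotype column, monomorphic SNP) still raises.
* Singular `V` raises `SingularVarianceError` naming the degeneracy by
  default.  An opt-in pseudo-inverse mode (`pseudo_inverse=True`,
  `--pseudo-inverse`) uses the Moore-Penrose inverse with
  `df = rank(V)` and flags the result; it is opt-in because silently
  changing the reference distribution is worse than failing.
* P-values below 2.22e-16 (double-precision epsilon — the resolution limit
  of a survival probability computed as `1 - CDF`) are reported at that
  floor with a `p_floored` flag; the raw value is retained in `p_raw`.
* Missing data: complete-case by default.  An optional prevalence-based
  phenotype imputation offers a seeded Bernoulli draw (binary output) or a
  deterministic expected-value fill (fractional output; the score algebra
  does not require integrality, and datasets accept fractional phenotypes
  when explicitly flagged).

## The PheWAS baseline

The comparator fits one logistic regression per phenotype (statsmodels
MLE), Bonferroni-adjusts the `q` Wald p-values, and declares pleiotropy
when the minimum adjusted p-value is below alpha.  Wald rather than
likelihood-ratio p-values are used because inverse-variance weighting
consumes beta/se pairs.  Multi-site integration is mega-analysis (pool
rows, fit once) or fixed-effect IVW meta-analysis (fit per site, weight by
`1/se^2`).  Sites whose fit separates or fails to converge are flagged and
excluded from the meta-combination rather than aborting the analysis —
small sites with rare alleles separate routinely.

## What the generator emulates

The synthetic-data module reproduces the evaluation conditions:

* genotypes i.i.d. from Hardy-Weinberg proportions at a chosen MAF
  (per-site MAFs allowed, e.g. 0.05/0.1/0.4 heterogeneity);
* phenotypes Bernoulli from the logistic model above with intercept
  `beta0 = -0.5` (≈ 37.8% baseline prevalence, i.e. "~40%");
* effect patterns: `same` (all `beta_ref`), `opposite` (first half
  `+beta_ref`, second half `-beta_ref`; odd `q` puts the extra phenotype in
  the positive half), `sparse` (decay `2^-i * beta_ref`, i = 1..q — the
  printed decay formula is self-referential, so a `sparse_from_one` switch
  provides the `2^-(i-1)` reading; the two differ only by a factor of 2 in
  scale), `null`;
* optional covariates: gender ~ Bernoulli(0.5) with effect `gamma = 0.1`,
  age ~ Normal(65, 20) with effect `delta = 0.05` entering the generator
  continuously, while the emitted strata cross gender with the discretized
  age bins (<50 / [50, 75) / >=75) — mirroring an analysis that can only
  adjust categorically;
* optional phenotype correlation via a Gaussian copula: latent
  `z ~ N(0, R)`, `Y_j = 1` iff `Phi(z_j) < expit(eta_ij)`.  This preserves
  the logistic marginals exactly for any `R`; realized binary-scale
  correlations are attenuated relative to the latent ones.  The default
  `R` has two equal blocks with within-block latent correlation 0.5 —
  the reference design shows two correlated disease clusters but prints no
  numeric values, so 0.5 is a package default, configurable via
  `block_correlation(q, rho)`.

What the generator does not emulate: linkage disequilibrium between SNPs,
population structure and relatedness, genotyping/imputation error, dosage
uncertainty, site-level effect heterogeneity, informative missingness of
EHR phenotypes.  Passing tests therefore demonstrate correctness of the
algorithm and calibration under the stated sampling model, not robustness
to those real-data complications.

## Monte-Carlo harness

Power and type-I error are estimated as rejection percentages over
repeated simulation.  A master seed spawns one substream per repetition
(`numpy` SeedSequence), and all methods in a comparison evaluate the same
realized dataset within a repetition, so method contrasts are paired and
the distributed/pooled arms reject identically by the lossless property.
Default repetition counts are 200 for power grids (Monte-Carlo SE <= 3.5
points) and 1000 for calibration checks; both are plain arguments.

## Known limitations and observed behavior

* The joint q-df score test is most powerful when association is spread
  across many phenotypes.  Under sparse alternatives (one dominant
  effect), and under strong positive phenotype correlation combined with
  same-direction effects, the Bonferroni min-p PheWAS baseline can match
  or exceed its power: correlation inflates the empirical variance of the
  summed score while leaving each marginal test untouched.  The package's
  own paired power comparisons (see `tests/test_acceptance.py` and
  `sumshare power`) exhibit exactly this regime structure.
* The test is asymptotic; with very rare variants and small pooled samples
  `V` becomes ill-conditioned before it becomes exactly singular, and the
  chi-square approximation degrades.  No small-sample correction is
  applied.
* Homogeneous effects across sites are assumed; under heterogeneity the
  test targets an averaged effect.
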