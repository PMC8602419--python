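# Methods

## The biometric model

Every analysis rests on the classical twin decomposition of a quantitative
trait into additive genetic (A), shared-environment (C), dominance (D) and
unique-environment (E) latent sources.  The identifying assumptions are the
standard ones: MZ co-twins share all segregating genetic variation and DZ
co-twins half of the additive part (a quarter of the dominance part); both
zygosities share environment to the same degree; E (which absorbs
measurement error) is individual-specific.  Because all pairs are reared
together, C and D are not jointly identified and the model space is
restricted to ACE, ADE and their submodels.

Models are parameterized on raw path coefficients (a, c or d, e) whose
squares enter the variances, which keeps every variance component
nonnegative without bound constraints; reported components are the squared
paths normalized by total variance, so a fitted a²+c²+d²+e² sums to 1 by
construction.  Path signs are unidentified and canonicalized to be
nonnegative after fitting.

## Likelihood and estimation

Each complete twin pair is one draw from a bivariate normal with a
group-specific mean vector and the model-implied 2×2 covariance (4×4 for
the bivariate Cholesky model).  The -2 log-likelihood is evaluated from
per-group sufficient statistics (pair count, mean vector, ML scatter
matrix), which is algebraically identical to summing per-pair densities
and makes repeated evaluation cheap; the identity is verified against a
brute-force per-pair summation in the test suite.  A non-positive-definite
implied covariance yields an infinite (internally, a large finite)
objective value rather than an exception, so the optimizer simply rejects
the point.

Optimization is quasi-Newton (L-BFGS-B) from three fixed starting points —
an even variance split, an A-heavy split (0.7) and an E-heavy split — so a
given dataset always produces the same fit regardless of seed or pair
order.  Convergence requires a projected-gradient norm below 1e-6 with a
relative objective tolerance of ~1e-12; disagreement above 1e-4 between
restart optima is flagged.  Estimation uses complete pairs only, mirroring
the removal of twins without co-twin information from the genetic
analyses; descriptives and PGS regressions use every individual.

Group structure by sex handling:

* **pooled** — one parameter set; sexes merged within zygosity and
  opposite-sex DZ pairs treated as DZ;
* **stratified** — independent per-sex parameter sets over the four
  same-sex groups; opposite-sex pairs are excluded (their likelihood would
  otherwise couple the sexes);
* **sexlim** — per-sex parameters joined through the opposite-sex DZ
  group, whose cross-twin genetic covariance is ½·r_g·a_m·a_f with the
  cross-sex genetic correlation r_g fixed (default 1) or free.  The
  sex-limitation tests of interest are the r_g = 1 restriction and the
  equality of per-sex component magnitudes; both are available as
  likelihood-ratio comparisons.

The saturated reference model frees the mean per group and birth order and
the full per-group covariance; its ML solution is closed form (sample
moments), and likelihood-ratio tests of structured models against it
implement the equal-means/equal-variances assumption checks.  Variance
-component tests are reported against the plain chi-square reference, the
convention of the model-fit tables this package mirrors; because the null
value of a variance component lies on the boundary of the parameter space
that reference is conservative, so the 50:50 chi-square-mixture p-value is
attached alongside for single-df comparisons.  A Monte-Carlo test in the
suite records the consequence: testing AE against ACE under an AE truth
rejects at roughly half the nominal rate.

## Confidence intervals

CIs for standardized proportions are profile likelihood: the set of values
whose profiled -2lnL lies within the chi-square(1) quantile of the
minimum, located by bisection to 1e-5 on the proportion scale and clipped
to [0, 1]; estimates pinned at a boundary produce one-sided intervals with
a flag.  For AE models the inner profiling step is closed form: with the
standardized a² fixed, the implied pair correlations are known, the GLS
mean has an exchangeable-correlation closed form and the total variance a
one-line ML solution.  This makes a univariate profile CI essentially
free, which the calibration studies exploit (95% intervals cover the
generating a² at 94-95% in 500-replicate checks).  Other models re-fit the
remaining parameters numerically at each profiled point.

In the bivariate model, r_A and r_E intervals are profile likelihood on
the correlation itself (the A or E covariance block is re-parameterized as
two component SDs plus the fixed correlation, and the remaining seven
parameters are re-minimized per point, warm-started along the bisection
path with a fall-back restart from the MLE to avoid bad basins).  The
phenotypic-correlation interval is delta-method (numerical Hessian of the
-2lnL, parameter covariance 2·H⁻¹), a pragmatic choice since r is a smooth
function of all eight parameters and is never near its boundary in
realistic data.

## Bivariate decomposition conventions

From the fitted lower-triangular paths, r_A = (A·Aᵀ)₁₂ / √((A·Aᵀ)₁₁(A·Aᵀ)₂₂)
and likewise for r_E; the phenotypic correlation satisfies the exact
reconstruction identity r = r_A·√(h₁²h₂²) + r_E·√(e₁²e₂²), asserted at
1e-8 on every fit.  The fractions of r attributed to genes and unique
environment sum to 1 but are deliberately not clamped to [0, 1]: when the
genetic and environmental contributions have opposite signs the genetic
fraction exceeds 1 and the environmental fraction is negative, a known and
meaningful configuration.  When r = 0 the fractions are undefined and
returned as NaN with a warning.  Worked-example checks that start from
printed two-decimal component estimates use an absolute tolerance of
0.015, the propagation of half-unit rounding in the inputs.

## Cluster-robust polygenic-score inference

Scores are standardized to sample SD 1 (n−1 denominator) within the
analysis stratum, so slopes are trait units per 1 SD of score.  Slope
variances use the cluster-sandwich estimator over twin pairs with the
standard small-sample factor G/(G−1)·(N−1)/(N−k) and a t(G−1) reference
(delegated to statsmodels, whose implementation was verified against a
hand-computed sandwich and shown to reduce exactly to HC1 for singleton
clusters).  Per-score R² is the squared trait-score correlation — one
score per model, not incremental.  The sex-interaction test is a clustered
Wald test of the sex-by-score coefficient in the pooled model; its size is
0.05 ± 0.02 in 500-replicate null simulations.

## The synthetic-data generator

The generator draws latent factors per pair with the cross-twin
correlations above (A factors correlate ½·r_g across opposite-sex pairs),
mixes them through lower-triangular Cholesky factors of user-supplied
genetic (rA) and environmental (rE) cross-trait correlation matrices, and
maps the standardized result affinely to per-sex means and SDs — so scale
and structure never confound.  Singletons are generated as full pairs with
one member deleted, giving the complete-pair filter real work.  Polygenic
scores are built from the individual's standardized additive-genetic
deviate plus an independent pair-correlated genetic factor, weighted so
the population R² with the target trait equals the requested value within
each sex; a request exceeding the trait's heritability is rejected, since
a genetic score cannot explain more than the additive-genetic share.

The default study configuration (`soctwin.study`) emulates the cohort
design the package targets: 254/176/156 complete pairs plus 121
singletons; per-sex means, SDs and AE heritabilities for SOC, depression
and neuroticism taken from the published descriptive and variance
-component tables; SOC-trait genetic correlations −0.84/−0.85 and
environmental correlations −0.43/−0.59 (the published women's values, the
sexes being reported as very similar); and PGSs explaining 3% of SOC
variance.  The depression-neuroticism factor correlations are not
published and are set to plausible positive values (rA 0.70, rE 0.45)
consistent with positive-definiteness.

What the generator does **not** emulate: genotype-level data (no SNPs or
LD — scores are simulated at the score level), non-normal questionnaire
scale distributions (floor/ceiling effects, item-level structure),
missing-at-random patterns beyond whole-individual deletion, age
structure, or assortative mating and gene-environment correlation, all of
which the biometric model itself also assumes away.  Passing recovery
tests therefore demonstrates correctness of the estimators under the
model, not robustness of the model to real questionnaire data.

## Problem sizes and numerical choices

Simulation studies in the tests use the study's own design (254/176/156
pairs) for bias checks at a² ∈ {0.2, 0.4, 0.6} with 200 replicates each;
1000 pairs with 500 replicates for CI coverage; 4000 pairs per zygosity
group for bivariate recovery (tolerance ±0.05 on r_A); 5000 individuals
for PGS R² recovery; and 500 null replicates for test-size checks, sizes
at which Monte-Carlo error is comfortably inside the asserted bands.
Bisection tolerances are 1e-5 (proportions) and 1e-3 (correlations, which
are reported at two decimals).  Ties between ACE and ADE at identical
-2lnL resolve to ACE and are flagged.  Degenerate saturated-model groups
(fewer than two pairs or singular covariance) are dropped with a warning;
identification failures (e.g. an AE fit without DZ pairs) raise before
optimization.

## Known limitations

* FIML for singletons is not implemented; incomplete pairs are excluded
  from likelihoods (the univariate means are well estimated anyway, and
  the emulated study likewise excluded them).
* The phenotypic-correlation CI is Wald rather than profile likelihood.
* No information-criterion model selection, bootstrap CIs, trivariate or
  higher Cholesky, or direction-of-causation models.
* The E-only model reports total variance as e² and is intended only as
  the bottom rung of the nesting ladder.
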