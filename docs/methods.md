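# Methods

## The generative and inferential model

The observation unit is the individual terminal shoot (10 surveyed per
tree), because the response is galls per shoot and tree is a random
effect above it. Counts for one gall type (a species × generation unit:
a species' spring sexual and autumn asexual galls are distinct
responses) across both survey years are modelled as

    y_i ~ Poisson(exp(eta_i))
    eta_i = x_i'B + u_prov(i) [+ u_nugget(i)] + u_zone(i) + u_plot(i)
            + u_tree(i) + e_i

Fixed effects are an intercept, a two-level year factor (treatment
contrasts, first level as reference) and, for phenotype models,
budburst, budburst², DBH, form and their pairwise interactions. Random
effects are provenance, soil zone, plot and tree; `e_i` is the
observation-level UNIT effect that absorbs overdispersion and is always
present for the Poisson family. Gaussian responses (e.g. DBH as a
trait model) use the same machinery with `e_i` as the residual.

Provenance nonindependence is encoded in the structured term
`u_prov ~ N(0, sigma² C)`. Three structures are supported: the exact
identity (provenances independent), `1 − F_ST` from pairwise
Weir–Cockerham theta, and `1 − GeoF_ST` from the isolation-by-distance
regression. Structured models add an identity-structured provenance
nugget so level-specific variation beyond the correlation structure is
not forced into the structured term. The provenance component is
reported both separately (structured, nugget) and pooled, since a
single "provenance" value is what the headline comparison plots.

## Priors and their implementation

* Fixed effects: normal, mean 0, variance 10^8.
* Random-effect variances: scaled F(1,1) with scale 1000, implemented by
  parameter expansion — the term enters the predictor as `alpha * L xi`
  with `xi ~ N(0, V I)`, `V ~ IG(1/2, 1/2)` and `alpha ~ N(0, 1000)`.
  The implied prior on `sigma² = alpha² V` is exactly 1000·F(1,1),
  equivalently a half-t(1) (half-Cauchy) prior with scale sqrt(1000) on
  the standard deviation; the prior-only sampler is checked against the
  analytic F(1,1) quantiles in the test suite.
* Residual/UNIT variance: inverse-gamma with shape and scale 0.001.

`L` is a PSD-safe eigen square root of the structure matrix (`L L' = C`),
so singular structures (e.g. the all-ones limit of no differentiation)
need no inverse.

## MCMC scheme

Given the latent log rates, all location effects (fixed and random) have
conjugate Gaussian block updates: per-level scalar updates via grouped
sums for identity terms, a small multivariate draw for structured terms,
and a scalar conjugate update for each expansion parameter `alpha`. The
latent rates themselves are updated per observation with random-walk
Metropolis; the global step size is adapted toward ~44% acceptance every
50 iterations during burn-in and frozen afterwards, so a fixed seed
reproduces runs bit for bit. Variances are conjugate inverse-gamma.
With no random terms and the UNIT effect disabled, the Poisson model
degenerates to a GLM and is sampled by independence
Metropolis–Hastings from a Laplace proposal centred at the internal
Newton ML fit (acceptance ≈ 1), which the tests compare against an
external IRLS fit.

Two named schedules: `paper` (500 000 iterations, 50 000 burn-in,
sampling every 450 — the published analysis schedule) and `desk`
(20 000 / 5 000 / 15), both retaining 1000 draws. All routine fitting,
testing and the acceptance script use `desk`; a `smoke` schedule
(100 draws) exists for pipeline plumbing tests only. Rows with missing
values in any model column are dropped and counted on the result object.

## Reported quantities

* Variance components: per retained draw, each random variance
  (including UNIT) divided by the summed random variances and multiplied
  by `1 − RsqM`; per-draw components therefore sum to `1 − RsqM`
  exactly. Summaries are posterior means with central 95% intervals.
* Marginal R² (RsqM): per draw,
  `sigma²_f / (sigma²_f + Σ sigma²_random + sigma²_dist)` with
  `sigma²_f` the variance of the fixed-effect predictor over
  observations. For the log-link Poisson the distribution-specific
  variance uses the lognormal approximation `ln(1/lambda + 1)` with
  `lambda = exp(beta0 + Σ sigma²/2)` — the standard choice for this
  family.
* pMCMC: `max(2·min(P(draw>0), P(draw<0)), 2/n_draws)`.
* FDR: Benjamini–Hochberg and Benjamini–Yekutieli step-up adjustments
  (statsmodels), applied within one fixed-effect term across the family
  of gall types; the family definition is configurable since it is a
  reporting convention, not part of the model.
* Prediction curves: per draw
  `y(x) = exp(intercept + x·coef [+ x²·coef_sq] + 0.5·Σ sigma²)` — the
  lognormal mean correction over all random-effect variances. A flag
  exposes the literal variant in which the correction is additionally
  scaled by `x`, for sensitivity only.
* Survey summaries: totals, mean galls/shoot (= total / shoot records),
  incidence (proportion of shoots with ≥1 gall) and between-year ratios
  oriented larger:smaller and integer-rounded ("16:1", "1:8"); a zero
  (or underflowing) yearly mean renders the ratio undefined ("–"). A
  gall type is excluded by the incidence filter only when its incidence
  is below the threshold (default 1%) in *every* survey year.

## Population structure

Pairwise F_ST is the Weir–Cockerham (1984) theta: variance components
a, b, c computed per allele per locus and combined as
`Σa / Σ(a+b+c)` across alleles and loci (the fstat convention). Missing
calls are excluded per locus; loci where either population has fewer
than two genotyped individuals are skipped; negative estimates are
retained for the Mantel and regression stages (the estimator is unbiased
around zero) and clamped to [0, 0.999] only when a covariance is built,
so covariances stay in (0, 1].

The Mantel test correlates upper-triangle entries, permutes rows and
columns of one matrix jointly, and is one-sided (greater), matching the
isolation-by-distance hypothesis; the sampled p-value is
`(1 + #{r_perm ≥ r_obs}) / (n_perm + 1)`, with exhaustive enumeration
available for small matrices. The GeoF_ST regression is ordinary least
squares of raw pairwise F_ST on raw great-circle kilometres
(haversine, 6371 km sphere); log-distance and F_ST/(1−F_ST) variants are
exposed as options since the published form of the regression is not
recoverable. Predictions fill a complete symmetric matrix including
ungenotyped provenances; by default predictions replace observed values
everywhere (a flag restricts them to filling the missing provenances —
both behaviours exist because the published choice is unknown), and the
intercept's prediction at distance zero is clamped at 0 during
covariance construction.

`1 − F_ST` matrices built from noisy estimates are routinely slightly
indefinite; negative eigenvalues are clipped to zero, the matrix is
rescaled to a unit diagonal (which preserves PSD and bounds covariances
at 1), and the repair is flagged and logged, never silent.

## The synthetic generator

The generator emulates the study conditions: 20 provenances whose
origins span 15° latitude and 34° longitude around a Northwest-France
trial site, 5 soil zones, 2 study plots per zone per provenance, 24
trees planted per plot of which 12 are surveyed, 10 shoots per tree, two
survey years — 200 plots, 4800 trees, 2400 surveyed trees, 24 000 shoot
records per survey.

* Genotypes: per locus, log-scale allele frequencies are a shared base
  vector plus a per-allele Gaussian field over provenances with
  exponential correlation `exp(−decay·d_km)` (default range ~1500 km,
  amplitude 0.6, 4–8 alleles per locus, 24 diploids per provenance, 10
  loci). This yields mean pairwise F_ST ≈ 0.03 and a strongly positive
  Mantel correlation — the empirical premise the pipeline needs — while
  `decay = 0` collapses to a single shared frequency vector. No
  paper-side mechanism exists to copy; only this correlation had to be
  reproduced.
* Phenotypes: budburst is a latitudinal cline (default −0.15 score per
  degree; southern provenances flush earlier/higher) on a latent
  Gaussian rounded and clipped to 0–5; DBH declines with (geographically
  proxied) genetic distance from the local provenance; form is a
  baseline with noise, clipped to 1–10.
* Counts: the generative inverse of the GLMM above, with all realised
  effects returned for recovery tests. Surveys are balanced by design;
  the real study's unexplained shortfall of autumn shoots in one year is
  deliberately not emulated.

What passing tests show — and do not. Recovery and calibration results
demonstrate correctness of the estimator chain under its own generative
assumptions (log-linear effects, Gaussian random effects, Poisson
noise). Real surveys add unmodelled features: spatial autocorrelation
within the plantation, parasitoid-driven mortality, unbalanced effort,
zero-inflation beyond the lognormal-Poisson. Passing therefore
validates the software and the statistical machinery, not the biology;
in particular the published headline components (provenance explaining
3–33% under identity vs 38–95% under 1−GeoF_ST) cannot be reproduced
without the undeposited field data, and the package instead verifies the
qualitative pattern that structured models attribute more variance to
provenance.

## Problem sizes and numerical choices in the test suite

Parameter recovery runs 10 replicate trials of 24 000 shoot records
(one survey year, intercept-only truth: provenance 0.3, plot 0.2, tree
0.1, unit 0.4) at the `desk` schedule; recovery is judged on the
replicate-ensemble mean of each posterior-mean component (±0.10) and on
95%-interval coverage across term × replicate cases (≥90%). The
covariance contrast uses 5 replicate reduced trials (3200 records: 4
trees per plot, 4 shoots per tree) and requires the structured model's
provenance component to exceed the identity model's in ≥80% of
replicates. Mantel calibration uses 500 null replicates at 99
permutations. These sizes are the package's own choices for routine
verification; the generator scales to the full design.

Degenerate inputs are handled explicitly rather than numerically:
constant matrices are rejected by the Mantel test, zero-variance
Gaussian responses and non-integer Poisson responses raise, perfectly
collinear fixed effects raise an aliasing error naming the columns, and
proposals for the latent log rates are clipped at ±30 to keep `exp`
finite.

## Known limitations

* Single-chain sampler; between-chain R-hat is not available (ESS and
  Geweke diagnostics are).
* No negative-binomial or zero-inflated families; overdispersion is
  carried entirely by the UNIT term.
* GeoF_ST inherits the weak resolution of the F_ST–distance regression;
  with shallow differentiation the structured and identity models are
  only weakly distinguishable, which is precisely the motivation for
  reporting both.
* The Gaussian-field genotype generator produces equilibrium
  isolation-by-distance patterns only; it does not model drift,
  bottlenecks or marker-specific mutation.
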