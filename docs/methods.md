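# Methods

This note documents the models implemented in `dietscore`, the defaults
chosen where the design was genuinely open, and what the synthetic-data
tests do and do not demonstrate about real survey data.

## 1. The estimation problem

Dietary surveillance data arrive as survey summaries: for each survey,
stratum and dietary factor, a sample mean, SD and participant count.
Surveys differ in assessment method (24 h recall, FFQ, DHS-style
questionnaire, household budget survey), representativeness, and in how
finely they stratify the population.  The target of inference is the
mean intake of each factor in each of 264 demographic strata (2 sexes ×
22 age bands × 3 education levels × urban/rural) of every country-year,
with honest uncertainty — including for strata and country-years no
survey ever observed.

## 2. First-stage intake model

The model is specified in `dietscore.model` (see the module docstring
for the formula).  Key choices:

**Log scale.**  Intakes are strictly positive and right-skewed; the
model works on the log of the observed sample mean, with the
delta-method observation variance `(SD²/n)/mean²`.

**Variance pooling and the delta correction.**  Per-record variance
estimates are noisy (a 24-df SD estimate has ~30% CV) and, for
log-normal data, positively correlated with the observed mean.  Using
them raw in 1/v weights biases every weighted mean downward by 1–2% —
comparable to the posterior width at desk scale.  The model therefore
pools the relative variance `SD²/mean²` within each survey and applies
the second-order correction `E[log(sample mean)] = log(true mean) − v/2`.
Both behaviours are `ModelSpec` switches (`pool_variances`,
`delta_correction`), on by default.

**Random-effect structure.**  Nested mean-zero effects for region,
country, country-year and survey.  The country-year term absorbs
country-specific departures from the shared time trend (real countries
do not share one slope); the survey term, with a scale estimated per
assessment method, absorbs between-survey heterogeneity beyond sampling
error.  Without these two terms the posterior treats observation
variances as exhaustive and its intervals become overconfident by a
factor of several — interval coverage of true stratum means collapses
from ~95% to under 10% in simulation.  Overdispersion for
non-representative or coarsely stratified surveys is additionally a
variance multiplier `phi = 1 + delta`, `delta ~ HalfNormal(1)`, applied
to those records only.

**Age curve.**  A natural cubic spline over the 22 age-band midpoints
with knots at every third midpoint, QR-orthonormalized over the
evaluation points.  Orthonormalization matters: the raw truncated-power
basis is so collinear that a weakly-informative prior on its
coefficients visibly distorts the fitted curve.

**Fixed effects and priors.**  Sex, education, urbanicity, a linear
per-decade time term, a country-year covariate slope, and per-method
bias coefficients relative to 24 h recall.  Priors are
weakly-informative normals (SD 10 for the intercept, 1–2 for everything
else, on the log-intake scale) and half-normals (SD 0.5–1) for scale
parameters.  All are `ModelSpec` fields and deliberately swappable; no
claim of fidelity to any particular production system's priors is made.

**Collapsed strata.**  A record whose survey did not stratify by, say,
education is linked to the model as the person-weighted average of the
constituent strata's linear predictors.  This equates a weighted
average of log means with the log of the weighted mean; the
approximation error is half the within-group variance of log means
(≈0.005 at the defaults) and is absorbed by the overdispersion term.

**Sampler.**  Conditional on the scale parameters the model is
linear-Gaussian, so all location parameters (fixed effects plus every
random effect) are drawn jointly from their exact multivariate-normal
conditional each sweep.  Because observation weights depend on the data
only through the scalar overdispersion multiplier, the Gram matrices
are precomputed once and each sweep costs O(q³) for q parameters.
Scales move by adaptive random-walk Metropolis on the log scale,
followed by an ancillarity–sufficiency interweaving step (holding
u/sigma fixed, sigma is a regression coefficient with a Gaussian
conditional) that eliminates the funnel stalling centered Gibbs when a
scale approaches zero.  Four chains × 500 warmup + 1,000 retained
sweeps give the 4,000 posterior draws used everywhere downstream; that
count is enforced as a pipeline invariant.  Split-R̂ and effective
sample size (via arviz) are computed for all fixed effects and scales;
R̂ > 1.05 is flagged, never silently accepted.  Scale parameters whose
true value is at the zero boundary (e.g. the 24 h-recall survey scale
in bias-free simulations) mix slowly and are routinely flagged; their
posterior mass is piled near zero and predictions are insensitive to
them.

**Prediction.**  Stratum predictions are made at the reference method
with survey effects at zero.  A country-year without data receives a
fresh country-year effect from its posterior scale; a country never
observed receives the region-level predictive distribution (region
effect plus a fresh country effect) — identical parameters for every
unseen country of a region.  Percentile summaries (median, 2.5th,
97.5th) use linear interpolation between order statistics, the same
convention as the sort-based oracle in the tests.

## 3. Second-stage time model

Per factor, the national log-mean series (mean over strata of the log
intake, per draw) is modelled as country lines `a_c + b_c (t − t̄)` with
`(a_c, b_c) ~ MVN(mu, Sigma)`; `Sigma` (inverse-Wishart, df 4, scale
diag(0.1², 0.01²)·4) carries the cross-country intercept–slope
correlation.  An optional global covariate slope uses food-availability
series; countries without covariate coverage are excluded and keep
first-stage draws.  Adjustment replaces, draw-wise, the first-stage
country-year level with the smoothed level, preserving within-level
stratum structure and draw alignment.

## 4. Energy standardization and scoring

Intakes are rescaled to 2,000 kcal/day by the density method applied per
draw: each absolute-unit factor draw is multiplied by
`2000 / energy-draw` of its stratum; energy maps to exactly 2,000 and
energy-relative units (% energy, ratios) are untouched.  Draw-wise
scaling (rather than scaling summaries) is what keeps uncertainty
propagation intact; it exactly preserves within-draw ratios between
mass-unit factors.  Whether a production system standardizes draws or
summaries is generally unstated; draws are the conservative choice.

Patterns are data, not code: YAML definitions list components with a
direction and a rule.  AHEI uses fixed linear cutpoints (0 points at the
worst cutpoint, 10 at the optimal, linear and clamped between; mirrored
for unhealthy components; sum × 100/90).  The shipped cutpoints follow
the published AHEI-2010 shapes expressed in this package's factor units
and are editable.  DASH (Fung 8-component form) and MED (Trichopoulou
form without alcohol) use empirical cutpoints: sex-specific quintile
boundaries / medians of the population-weighted distribution of
stratum-level posterior-median intakes, pooled across countries,
computed once for the 2018 reference year and reused unchanged for all
years.  Weighted quantiles are left-continuous (type 1); a value tied
with a boundary takes the lower quintile, a rule that is
direction-independent and keeps five equal-weight strata on distinct
points.  Median rules award the point only strictly beyond the median.
Alcohol and trans-fat components are not estimable from these data and
are excluded by construction.

## 5. Aggregation

All estimates are formed draw-wise: weighted mean over included strata
per draw, then median/2.5th/97.5th over the 4,000 aggregated values.
Weights renormalize within any population filter, so estimates are
invariant to weight rescaling, and the global aggregate equals the
population-weighted aggregate of regional aggregates exactly, per draw.
Subgroup contrasts difference matched stratum pairs per draw (education:
≥12 y minus <6 y, the middle level excluded; pair weight = summed person
count of the pair); 1990→2018 changes difference per stratum per draw
and aggregate with 2018 weights only, so demographic drift cannot
masquerade as dietary change.  Draw `d` is assumed to index the same
joint posterior sample everywhere — a contract the IO layer preserves by
storing draw order.  Spearman correlations between patterns are
computed across strata on stratum-level median scores.

## 6. The synthetic world

`dietscore.world` generates the study frame the estimator assumes:
regions → countries → 264 strata, with per-factor true surfaces built
additively on the log scale from mean-zero region/country effects
(SD 0.20/0.12), sex/education/urbanicity effects (SD ~0.1), a smooth
age curve (values at five anchor ages, SD 0.2, monotone-cubic
interpolated), and country time slopes (mean slope SD 0.004/yr, country
SD 0.002/yr, intercept–slope correlation 0.3).  Individual intakes are
log-normal (within-stratum log-SD 0.5); surveys observe sample means of
n individuals (default 25 per stratum) times a method bias, plus a
survey-level log-normal shift (method-dependent SD 0–0.12,
non-representative surveys +0.10 in quadrature).  Default method biases
(FFQ 0.92, DHS 0.85, HBS 1.15) are placeholders with the conventional
direction of concern — the magnitude of real survey-method biases is
unknown and nothing downstream depends on these values.  Covariates are
the true country-year log-mean deviation plus noise (SD 0.05),
emulating availability data.  The default desk scale — 3 regions × 4
countries × 10 factors × 4 years — keeps a full fit around three
minutes on one CPU; these sizes are also what the recovery tests use.

What passing recovery tests show: the estimation machinery is
internally consistent — when data arise from the assumed process,
intervals cover, planted biases are recovered, cross-validation tracks.
What they do not show: robustness to real-world violations the
generator omits — zero-inflated intakes, seasonal effects, correlated
multi-factor reporting errors, informative survey placement, biomarker
calibration, or misreporting that varies with body size.  Zero
inflation in particular is excluded by design: the model targets
strictly positive stratum means.

## 7. Numerical details and degenerate inputs

- Observation variances are floored at 1e-7 (log scale); SD-zero records
  are accepted and dominated by the floor.
- Exactly 4,000 retained draws is asserted at every stage boundary.
- Degenerate (all-equal) quantile distributions emit a warning and give
  non-increasing boundaries; scoring still works (every value ties low).
- Empty filters, zero-population filters, missing years, missing energy
  draws and unknown categorical codes are hard errors; strata that
  cannot be standardized or scored are dropped with a logged count,
  never silently imputed.
- Cross-validation reshuffles once if a fold empties a country or
  factor from the training set, then errors.

## 8. Known limitations

- The overdispersion multiplier is shared across all flagged records of
  a factor rather than varying by survey quality tier.
- The second-stage model smooths national levels; it does not re-shrink
  stratum-level contrasts within a country-year.
- Education assignment for child strata follows the survey's own coding;
  no parental-education imputation is attempted.
- The sampler's boundary-scale mixing (section 2) inflates R̂ on
  near-zero variance components; a collapsed (marginalized) scale update
  would fix this at some implementation cost.
- With many country-years × factors, `predict_strata` on all targets at
  once holds all draws in memory (~8.5 MB per country-year-factor);
  chunk by country or factor for large worlds.
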