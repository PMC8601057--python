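# Methods

## The model

`ploveripm` fits an integrated population model (IPM) to three snowy plover
(*Charadrius nivosus*) breeding populations (Texas, New Mexico, Oklahoma)
observed over 1998–2018.  A single latent abundance process ties together
four data streams that were collected in only partially overlapping
region–year sets: shoreline population counts, grid/distance-sampling
counts, nest records, and capture–recapture–resight histories.

### State process

Let N_{i,t} be the (continuous, positive) population size of region *i* in
year *t*.  The first year is anchored at
log N_{i,1} ~ Normal(mu0_i, 0.1), with mu0_i derived from the region's
first available survey data (see *Initial-state anchor* below).  Thereafter

log N_{i,t} = log( N_{i,t-1} · 0.5 · phi^{AM}_{i,t-1}
             + N_{i,t-1} · 0.5 · phi^{AF}_{i,t-1}
             + N_{i,t-1} · 0.5 · gamma_{i,t-1} · pi_{i,t-1} · 0.5 · phi^{JM}_{i,t-1}
             + N_{i,t-1} · 0.5 · gamma_{i,t-1} · pi_{i,t-1} · 0.5 · phi^{JF}_{i,t-1} )
             + eps^N_{i,t},   eps^N ~ Normal(0, sigma_N),

i.e. both the adult sex ratio and the clutch sex ratio are 1:1, all
juveniles recruit at age one, and immigration is ignored.  gamma is average
clutch size, pi clutch success, and phi^C apparent survival of cohort C in
{AF, AM, JF, JM}.

### Observation models

* Shoreline counts (Texas, New Mexico), one row per lake and date:
  y ~ Poisson(N_{i,t} · exp(eps^y) · p_count), with one local deviation
  eps^y ~ Normal(0, sigma_y) per lake-date row.
* Oklahoma grid counts: y ~ Poisson(N_{i,t}/668 · exp(eps^y) · p_count)
  with one eps^y per grid-year; distance-sampling rows replace p_count by
  exp(-xi·d) at the row's recorded distance.  The count-survey detection is
  tied to the decay at the 30 m median distance, p_count = exp(-30·xi).
* Nests: clutch size n in {1,2,3} follows a multinomial logistic
  regression with baseline category 1 — log theta^{[n]} = alpha^{[n]} +
  beta^{[n]}·(PDSI, MINT, WIND) + eps^{[n]}, omega^{[n]} =
  theta^{[n]} / (1 + theta^{[2]} + theta^{[3]}), gamma = 1·omega^{[1]} +
  2·omega^{[2]} + 3·omega^{[3]}; clutch fate is Bernoulli(pi) with
  logit(pi) regressed on the same standardized covariates.
* Encounter histories: Cormack–Jolly–Seber conditioned on first capture.
  Survival over the interval (t-1, t) uses the year-t covariates.  A bird
  marked as a juvenile uses juvenile survival for its first interval and
  the same-sex adult survival afterwards.  Recapture and resight combine
  into a single per-occasion detection p* = 1 − (1−p_rec)(1−p_res),
  constant over time and regions.

All regression intercepts/slopes are shared across regions by default
("universal" variant, the information-borrowing configuration);
region-specific intercepts and slopes are available via
`ModelOptions(universal_slopes=False)`.

### Covariates

Breeding-season means of the Palmer drought severity index (wetland
availability proxy), minimum temperature and wind speed per region-year,
consumed as annual values.  Covariates are z-scored with the pooled mean
and pooled sample SD (n−1) across all region-years, so that universal
slopes act on one shared scale.  Actual evapotranspiration, precipitation
and maximum temperature are excluded (collinear with PDSI/minimum
temperature).

### Priors

Normal(0, variance 100) on every intercept and slope; Gamma(0.01, 0.01) on
every precision 1/sigma² and on the decay xi; Uniform(0, 1) on p_rec and
p_res.  The survival process SD is cohort-specific by default, with a
shared-SD switch.

### Initial-state anchor

mu0_i is not estimated: it is log of a population-scale count estimate in
the region's first data year (max shoreline count, or n_grids × mean
grid-level count) divided by the count detection at the *current* decay,
i.e. mu0_i(xi) = log(count anchor) + 30·xi.  Making the anchor track the
decay keeps it from spuriously pinning xi at whatever value was used to
pre-compute it.  Without any count data the anchor is a fixed constant and
the decay reverts to its prior.

## Inference

The posterior is sampled by a Metropolis-within-Gibbs scheme written
directly against the joint density (no external PPL):

* **Alive-state augmentation.**  The latent alive/dead state behind each
  encounter history is imputed by forward-filtering/backward-sampling;
  marginally this reproduces the closed-form CJS recursion (verified by
  enumeration in the tests), and conditionally it reduces every survival
  update to a binomial likelihood on at-risk/survived counts.
* **Vectorised elementwise updates** for the process-error fields, the
  local count deviations and the latent log-abundances (red/black over
  years, since the state process couples only adjacent years).
* **Adaptive-covariance blocks** for each (intercept, 3 slopes) regression
  block: the empirical covariance is learned during burn-in (Welford
  updates, scaled 2.38²/d) and frozen afterwards.
* **Conjugate Gibbs** draws for all precisions.
* **Interweaving (ASIS)** for every process SD: after the centred Gibbs
  draw, a non-centred move proposes a new SD while rescaling its whole
  error field, breaking the funnel between weakly-informed fields and
  their SDs.
* **Exact translation moves**: adding delta to a coefficient block while
  subtracting Z·delta (Z = [1, covariates]) from its error field leaves
  every demographic rate unchanged; the conditional of delta is Gaussian
  and is Gibbs-sampled.  This removes the dominant posterior correlation
  in the regression blocks.
* **Decay ridge move**: shifting xi and all log N jointly along the
  direction that keeps the constant-detection count terms invariant, so
  the decay mixes across its trade-off with absolute abundance.
* **Detection ridge move**: p_rec and p_res are separately unidentified
  given 0/1 histories (only p* enters the likelihood); a slide move along
  constant p* samples their conditional exactly.

Chain settings: the full-scale configuration (4 chains × 300,000
iterations, 50,000 burn-in, thin 100 — 10,000 retained draws) is supported;
the package default is a desk-scale 4 × 6,000 / 1,000 / thin 5
configuration under which the synthetic-study posterior passes the classic
Gelman–Rubin check (R-hat ≤ 1.05 for all scalar parameters).  Credible
intervals are central 80% intervals from linear-interpolation quantiles;
R-hat is the classic (non-split, non-rank-normalised) statistic.

## Post-fit analyses

* **Posterior predictive checks.**  Chi-square discrepancy for the pooled
  count and distance streams; Freeman–Tukey for clutch size, clutch fate
  and encounter data; the Bayesian p-value is the proportion of draws with
  strictly larger replicated than observed discrepancy.  For the count
  streams the check is *mixed*: the lake/grid-level deviations are redrawn
  from Normal(0, sigma_y) in the replicates and both discrepancies are
  measured against the marginal mean N·p·exp(sigma_y²/2).  Conditioning on
  per-row deviations would let each observation's own free parameter track
  it, pushing the p-value toward 1 even for a perfectly specified model;
  the mixed construction makes observed and replicated data exchangeable
  under the model and hence calibrated.  The encounter discrepancy
  compares per-occasion detection totals with their expectation given the
  alive states — the aggregation is a package choice, as no canonical one
  exists.
* **Hierarchical partitioning.**  Per posterior draw, annual growth
  N_{i,t}/N_{i,t-1} (pooled across regions) is regressed on the six
  demographic series (gamma, pi, four cohort survivals); the all-subset R²
  decomposition attributes to each predictor its average R² increment over
  all entry orders, reported as a percentage of total explained variance
  (summing to 100).  Constant predictors receive 0%; negative independent
  contributions (suppressor configurations) are floored at zero before
  renormalising, with a logged warning; exactly collinear varying
  predictors raise an error naming the subset.  R² is the goodness-of-fit
  measure and region-pooling the default, both exposed in code.
* **Standardized effect sizes.**  SES = |posterior mean| / (80% CI width);
  strong if SES > 0.6, moderate for 0.3 ≤ SES ≤ 0.6 (both boundary values
  classify as moderate), little-to-none below 0.3.

## Synthetic data

The generator runs the exact generative model forward, so fitted and
generating models coincide: AR(1) covariates per region (coefficient 0.3,
marginal SDs 2.0 / 1.5 / 0.8 for PDSI / minimum temperature / wind, then
pooled z-scoring of the realized sample), demographic rates from the
regressions with process-error draws, abundance propagated through the
state equation, and observations emitted only where the availability mask
is true.  The `study` mask preset reproduces the study's partial alignment
(e.g. Texas shoreline counts 1998–2000/2008–2010/2017–2018 only; Oklahoma
grid surveys 2013–2017, distance sampling 2017–2018).  Distance rows draw
their distances uniformly on [0, 75] m (the survey truncation distance).

Default true parameters mirror the study system: initial populations 150 /
60 / 2000 (TX/NM/OK), mean clutch size ≈ 2.6, clutch success ≈ 0.38, adult
survival ≈ 0.76–0.77, detection decay 0.020 per metre, and productivity
slopes at the magnitudes estimated for the real populations.  Juvenile
survival defaults (≈ 0.45 female, 0.35 male) are set above the real-data
posterior means — whose values would drive the simulated populations to
collapse within the 21-year horizon — giving a mild decline (lambda ≈
0.96) instead.  Per available region-year the defaults are 30 nests, 25
newly banded birds (cohort mix 30/30/20/20% AF/AM/JF/JM), weekly-scale
shoreline counts (8 dates × 3 lakes in Texas, 6 dates in New Mexico), 100
surveyed grids, and 9 distance-sampling grids × 4 visits.

What the generator does *not* emulate: movement between regions, observer
heterogeneity, within-season nest-survival dynamics, partial nest
mortality, and year-to-year variation in survey effort.  Passing recovery
tests therefore demonstrate correctness of the inference machinery under
the model's own assumptions, not robustness to their violation in field
data.

## Numerical choices

Linear predictors are clipped at ±35 before exponentiation; probabilities
are floored at 1e-300 inside logs; a zero Poisson rate contributes 0 (y=0)
or −inf (y>0).  Sampled SDs are bounded to [1e-6, 1e3] and detection
probabilities kept strictly inside (0, 1) — with no informing data the
vague priors otherwise let these wander beyond float range; the bounds are
far outside any data-informed posterior.  Latent abundances are continuous and never rounded.
Initialisation uses crude data moments (clutch frequencies, fate rate,
per-cell count-based abundance estimates interpolated across gaps) plus
chain-specific jitter; a non-finite starting density triggers
re-initialisation (up to 10 attempts).  Proposal scales adapt only during
burn-in.  All randomness flows from a single seed through
`numpy.random.SeedSequence` spawns per chain.

## Desk-scale problem sizes

The test suite exercises the pipeline at sizes chosen for a laptop-class
budget: the calibration/convergence fit uses 4 chains × 12,000 iterations
(2,000 burn-in, thin 5) on the study-pattern scenario — long enough for
the weakly identified juvenile-survival block to pass the R-hat check with
margin, still 25× below the full-scale setting; the recovery study uses 20
replicates at 2 × 2,000 / 700 / thin 2, which recovers productivity slopes
at near-nominal coverage.  The full-scale 300,000-iteration configuration
runs through the identical code path and is available from the CLI.

## Known limitations

* p_rec and p_res are reported but only their combination p* is
  identified by 0/1 encounter histories.
* The initial-state anchor is a modelling convenience; for regions whose
  first data arrive late (Oklahoma), the anchor transfers that year's
  abundance scale to 1998 and early-year estimates inherit its
  uncertainty floor.
* The count observation model treats every lake-date count as a replicate
  of the whole-region population; site-level abundance structure is
  absorbed into sigma_y.
* Hierarchical partitioning inherits the usual caveats of regression-based
  variance decomposition with correlated predictors.
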