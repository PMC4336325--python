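# Methods

This note records what `farmbird` computes, the assumptions behind each
stage, and the choices made where the design was genuinely open. Everything
stated here is computed by the package's tests or pipeline; nothing is an
external empirical claim.

## Abundance model

The core is a Poisson GLMM with log link. Regional abundance (the summed
point counts of a species in one region and year) gets a linear predictor
with an intercept, climatic suitability, farmland-habitat proportion,
survey effort (number of farmland count points) and the crop shares as
fixed effects, plus Gaussian random intercepts for region, year and
observation. The observation-level random effect (OLRE) turns the Poisson
into a log-normal Poisson and absorbs extra-Poisson dispersion; it can be
switched off per fit.

**Effort as a covariate, not an offset.** Effort enters as `beta_3 x
n_points` on the log scale rather than as a `log(n_points)` offset. An
offset is the more common choice for count effort, but the covariate form
is the model this pipeline is built around, and it lets the data decide the
effort elasticity. Predictions for scenario comparisons hold effort at its
current value, so the choice does not affect projected changes.

**Estimation.** The marginal likelihood is approximated by the Laplace
method: for fixed variance parameters, the fixed effects and random-effect
modes are found jointly by damped Newton iterations on the penalized
Poisson log-likelihood (which is concave, so the inner problem has a unique
optimum), and the log-determinant correction is taken over the
random-effect block of the joint Hessian. The outer problem — at most three
log-standard-deviations — is solved by Nelder–Mead with warm-started inner
iterations. A smooth quadratic penalty outside the box log(sd) in [-8, 4]
keeps the surface informative when a variance collapses to the boundary;
a boundary estimate (variance ~ 0) is a legitimate converged fit. The
observation-level block of every linear system is diagonal and is
eliminated analytically, so one Newton step costs a dense solve of size
`p + n_regions + n_years`; indicator blocks are assembled with segment
sums rather than dense matrix products.

**Scaling and identifiability.** Continuous covariates are standardized
internally for conditioning and coefficients (with their standard errors,
via the full Jacobian transform of the covariance) are reported on the
original scale. Because the nine crop shares sum to one, the full crop
design plus intercept is singular; pipeline fits drop one crop
(`forage_crops` by default, configurable) as the reference category. Crop
coefficients are therefore contrasts against the reference crop;
predictions and projected changes are unaffected by which crop is dropped.

**Prediction.** Expected abundance is `exp(linear predictor)` with random
intercepts at their conditional modes for regions and years seen in
training and at zero (the population level) for new ones — in particular
the projection horizon, which is an unobserved "year". The OLRE is always
zero in prediction. At the joint mode the intercept's score equation makes
the conditional fitted values sum to the observed total, which is the
round-trip property the tests check.

**Diagnostics.** Overdispersion is the Pearson chi-square of the
conditional fit over residual degrees of freedom, where the denominator
subtracts both the fixed-effect count and the *effective* degrees of
freedom of the random effects (the trace of the shrinkage hat matrix,
`q - tr(D^-1 H_uu^-1)`); without that correction the ratio is biased below
1 on equidispersed data whenever clusters are small. R² for the mixed
model uses the latent-scale variance decomposition: marginal R² =
var(fixed predictor) / (fixed + random + distribution-specific variance),
conditional R² adds the random variance to the numerator. The
distribution-specific variance uses the log-normal approximation
`ln(1 + 1/lambda_bar)`; `lambda_bar` is taken as the mean marginal
expectation `exp(x'beta + sigma_tot^2/2)` averaged over rows (the choice
of lambda_bar is conventional; this one is stable when covariates vary).
Predictive power is a half-split check: fit on a random half of the rows,
predict the other half, and score `1 - SSE/SST` of observed against
predicted around the y = x line, retrying degenerate splits on fresh
substreams.

## Climatic suitability consensus

Distribution-model skill is the mean AUC over five random 70/30
calibration/evaluation splits (AUC is the probability a random presence
outranks a random absence, ties counted one half; splits whose test half is
single-class are redrawn, with a hard failure after 20 attempts). The model
used for projection is refit on all data. Projections are combined by
ranking models on mean AUC and weighting rank r proportional to
`1.6^(1-r)`, normalized; across climate-model/emission-scenario layers an
unweighted mean is used. The default order is SDM-weighted mean within each
layer, then the unweighted mean across layers; the reverse order is exposed
and agrees exactly whenever model ranks are shared across layers. Rank ties
break stably by model id. Weights are carried at full precision; two-decimal
rounding is reporting only — note that rounding the exact normalized weights
for 7 models gives 0.39 and 0.10 at ranks 1 and 4 where rounded reference
values of 0.38 and 0.09 are sometimes quoted; ranks 2, 3, 5, 6, 7 agree at
0.24, 0.15, 0.06, 0.04, 0.02.

The distribution models themselves are out of scope. The package ships one
deliberately simple plug-in (a logistic suitability learner) as harness
plumbing; anything implementing `fit`/`score_samples` can be swapped in.

## Spatial aggregation

Grid fields are downscaled to regions by overlap-weighted averaging with
region-normalized fractions (the share of the *region's* area in each
cell); a cell-normalized matrix violates the per-region sum-to-one
invariant and is rejected at construction. Cells referenced by the overlaps
but missing from a field are a hard error — silently renormalizing around
missing cells would bias suitability toward the observed cells. An opt-out
does not exist on purpose. The farmland-habitat proportion of a cell is the
sum of the three farmland land-cover classes (pasture, cultivated, mosaic),
capped at 1 since independent class layers can overshoot. Temporal and
scenario-layer averaging are plain element-wise means.

## Farmland-cover scenarios

A scenario is a deterministic relabelling of agroecosystems plus, per
target agroecosystem, bounds on crop shares (absolute, or relative to the
region's current share, with optional floor/cap), group constraints (e.g.
the cereal–oleaginous–proteaginous group), a primary-crop cap, and pinned
crops. The future composition minimizes the L1 distance to the current
composition over the feasible part of the 9-simplex — a minimal-disturbance
reallocation, solved as an LP (HiGHS). A feasible current composition is
returned unchanged. Ties among equally close solutions are broken by a
second LP maximizing permanent grassland within the optimal level set
(grassland retention); the quadratic-objective alternative was considered
and rejected to keep solutions at polytope vertices and reproducible.
Infeasible constraint sets raise a report naming the binding constraints
and the region.

Re-applying a scenario with *absolute* constraints to its own output is a
no-op. Current-relative constraints (e.g. "permanent grassland at least
1.2x current") deliberately re-resolve against the new composition, so
repeated application models a trajectory, not a projection.

The six built-in scenarios (status quo, global/regional biofuel, livestock
extensification, global/regional extensification) are YAML files. Two of
their numbers are fixed by the scenario narratives — a 5% permanent-
grassland floor everywhere under global extensification and a 45%
primary-crop cap in arable/mixed regions under regional extensification.
Every other multiplier is an interpretive encoding of the qualitative
scenario descriptions (marked as such in the files) and is expected to be
edited for real studies.

## Change statistics and guild comparisons

Abundance change is the symmetric ratio `(fut - cur) / ((cur + fut)/2)`,
bounded in [-2, 2] and antisymmetric; the (0, 0) pair is defined as zero
change (absent before and after). Driver decomposition predicts the future
abundance with only the drivers of interest (climate, farmland area,
farmland cover, or unions) set to future values, everything else held
current. Regional changes are aggregated with weights `area / n_points`.

The spread of a weighted mean uses the ratio-estimator variance for random
weights: with weighted mean `xw` and mean weight `wbar`,

    SEM^2 = n / ((n-1) (n wbar)^2) * [ sum (w_i x_i - wbar xw)^2
            - 2 xw sum (w_i - wbar)(w_i x_i - wbar xw)
            + xw^2 sum (w_i - wbar)^2 ]

and the reported SD is `SEM * sqrt(n_eff)` with Kish's effective sample
size `n_eff = (sum w)^2 / sum w_i^2`; with equal weights this reduces
exactly to the sample SD. The weighted one-sample t-test uses the same SD
and `n_eff - 1` degrees of freedom, reducing to the textbook test for
equal weights. Tukey HSD is the Tukey–Kramer procedure on the studentized
range distribution with pooled within-group variance; whether guild
comparisons should use weighted or unweighted group values is not settled,
so the group comparisons run unweighted by default and the weighted
machinery is exposed separately.

SSIg is the abundance-weighted mean of sub-habitat coefficients 4
(unimproved grassland), 3 (improved grassland), 2 (mixed), 1 (cropland),
with thresholds > 2.2 (grassland specialist) and < 1.8 (cropland
specialist) and mixed in between.

## Synthetic landscape

The generator draws what the analysis consumes, at the study's conditions:

- **Regions**: areas log-uniform on [11, 4413] km² (the span of French
  small agricultural regions; only the range is documented, so the
  scale-free log-uniform is used); agroecosystem labels arable/livestock/
  mixed with default probabilities 0.4/0.3/0.3 (echoing the roughly
  two-thirds cropland share of French agricultural area and the ~30%
  footprint of mixed systems); crop shares Dirichlet-distributed with
  agroecosystem-specific concentrations (livestock grassland-heavy, arable
  cereal-heavy).
- **Community**: farmland specialists with strong crop coefficients and
  spiky sub-habitat profiles, generalists with near-zero crop coefficients
  and even profiles; by default three farmland species are flagged as
  late-spring migrants whose first visit is uninformative. Random-intercept
  SDs default to 0.3 (region), 0.1 (year), 0.2 (observation).
- **Surveys**: squares of 10 points per region, roughly 10% of squares with
  fewer than 5 farmland points (so the farmland filter has work to do).
  The regional total for a species-region-year is one Poisson draw around
  the log-normal mean and is partitioned uniformly across the retained
  farmland points; the second visit carries a point's full annual count
  and the first a binomial thinning, so the max-of-two-visits rule
  recovers the latent count exactly and the prepared regional abundance
  keeps the generative distribution by construction. Points destined to be
  filtered out receive small independent stray counts. Real surveys differ
  in ways the generator does not emulate — detection varies between visits
  in both directions, within-region habitat heterogeneity structures the
  point allocation, and observer effects persist across years — so passing
  tests certify the statistical machinery, not field realism.
- **Grids and overlaps**: land-cover class fractions and per-species
  suitability per cell, with future suitability drifting downward on
  average (range retraction); each region overlaps 1–4 cells with
  Dirichlet fractions. Regions are abstract — no coordinates or polygons.

All randomness flows from a single seed expanded into named substreams
(`SeedSequence` spawn keys hashed from stage names), so stages can be rerun
independently and byte-identically.

## Verification sizes and numerical choices

The test suite checks, among others: Wald-interval coverage of the fixed
effects in 50 simulated datasets of 200 regions x 5 years at the default
variance components (>= 90% coverage required per coefficient); OLRE
variance estimated at <= 0.05 in >= 80% of 20 equidispersed datasets;
constraint satisfaction to 1e-8 on 1000 random feasible optimizer
instances and agreement of the L1 objective with an exhaustive
0.01-resolution grid search on 30 three-crop instances (instances are
drawn feasible-by-construction around a random target composition, with
constants on the 0.01 grid so LP vertices land on the oracle grid);
statistic oracles (brute-force AUC concordance, direct-formula weighted
mean/SD, scipy t-test, statsmodels Tukey) and 10^5-pair bounds/antisymmetry
checks of the symmetric change; byte-identical manifests for repeated runs
of the 50-region demo pipeline. Simplex sums are enforced to 1e-9
(generator) and 1e-8 (optimizer output, after clipping and renormalizing
the LP solution); linear predictors are clipped at ±30 before
exponentiation; near-singular Newton systems fall back to a Levenberg-style
ridge.

## Known limitations

- The Laplace approximation is first-order; for very sparse counts
  (mean << 1) its variance estimates can be optimistic. No adaptive
  quadrature is provided.
- The year random effect is estimated from few levels in typical runs
  (5 years); its variance is weakly identified and often lands on the
  boundary, which is reported as-is.
- Scenario constraint sets beyond the two pinned numbers are interpretive
  defaults, not calibrated to any census.
- No spatial autocorrelation, temporal trend, detection model or
  observer covariate; no economic feedback between scenarios and drivers.
- The pipeline's SDM stage is a harness around supplied projections;
  real ensemble modelling must be done upstream.
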