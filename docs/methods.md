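# Methods

This note records the modelling assumptions, the synthetic data-generating
process, the sampler design, and the numerical and design choices made where
more than one reasonable option existed.

## Models and priors

All four models are hierarchical Poisson regressions on an `N x T` panel of
strictly positive counts with log link and known offset (log exposure,
default zero). The fixed-effect vector `beta` (default 10 covariates) and
the overall intercept/slope of the linear-trend model carry improper flat
priors; their posteriors are proper in every configuration exercised here
because the likelihood is informative in those directions.

Spatially structured effects use the Leroux CAR distribution: a zero-mean
Gaussian Markov random field with precision `Q(W, rho)/k2`, where
`Q(W, rho) = rho (W_d - W) + (1 - rho) I`. Its full conditionals are

```
phi_i | phi_-i ~ N( rho * sum_j w_ij phi_j / (rho * m_i + 1 - rho),
                    k2 / (rho * m_i + 1 - rho) ),   m_i = sum_j w_ij.
```

Interpretation choices:

- `W_d` is the diagonal matrix of adjacency row sums (degrees). This is the
  only reading under which the printed full-conditional denominator
  `rho * sum_j w_ij + 1 - rho` follows from the joint precision.
- `rho = 1` (the intrinsic CAR) has a singular precision and no proper joint
  density; `car_log_density` refuses it. Samplers never touch it because
  every `rho` is given a uniform(0, 1) prior through a logit transform, so
  the boundary has measure zero and infinite transform cost.
- Isolated spatial units are allowed; their conditionals reduce to
  `N(0, k2/(1 - rho))`.
- Temporal structure uses the same machinery on the tridiagonal lag-one
  adjacency `Z`.
- The lag-one autoregressive model (TMS) reads the transition mean as
  `rho_T * a_(t-1)` (a multiplicative coefficient on the previous field).
- The separable model (STSM) has one variance `k2_t` per time point, each
  with its own inverse-gamma prior, and a single variance for the temporal
  trend.

Variance hyperpriors default to inverse-gamma IG(shape=1, scale=0.01), a
weakly informative standard for CAR variance components; both
hyperparameters are configurable (`PriorConfig`). Identifiability between
the intercept direction and the CAR main effects is handled by post-hoc
recentring of draws (`recenter_effects`): the effect means are folded into
the intercept terms without changing any fitted `log mu`, which is exact and
equivalent to constrained sampling for every summary reported here.

## Synthetic data-generating process

One replication at scenario `(sp, tm)`:

1. Per-unit 2-D coordinates drawn iid N(0, 1). The field never specifies a
   geography for synthetic units; coordinates exist to give the spatial term
   a location anchor and to build an adjacency.
2. Spatial noise `~ MVN(0, equicorrelation(N, sp))`, temporal noise
   `~ MVN(0, equicorrelation(T, tm))`. Compound symmetry is the unique
   exchangeable one-parameter correlation structure, hence the natural
   reading of "a correlation matrix with the specified correlation value".
3. Spatial term `s_i` = x-coordinate + spatial noise, constant over time;
   temporal term `t_t` = temporal noise, shared by all units. (An option
   redraws spatial noise each time point; it is off by default — the default
   decomposition is the one in which temporal noise is replicated across
   units.)
4. `log lambda_it = scale * (s_i + t_t - mean)`, with `scale = 0.5`. The raw
   sum of two unit-variance fields plus a coordinate has sd near 1.7;
   exponentiating it unscaled produces intensities spanning several orders
   of magnitude and, at strong correlation, overflow. Centring and halving
   keeps counts in the low single digits (matching a per-capita severe
   food-insecurity rate scaled to a small index) while preserving the
   correlation structure exactly. A hard guard (`latent_bound = 10`)
   rescales and logs any replication that still escapes.
5. Counts are zero-truncated Poisson draws (`y >= 1` enforced by rejection,
   with an inverse-CDF branch below intensity 0.1 where rejection would
   stall). Truncation, rather than adding one, preserves the stated
   mean-around-lambda relationship.
6. Ten covariates are built by orthogonalizing iid normal columns against
   the constant and each other (QR), then standardizing. All pairwise
   correlations are zero to round-off, so every variance inflation factor is
   exactly 1 — the property the original covariates (varimax-rotated
   principal components) were selected for. The covariates do **not** enter
   `lambda`: the generating process defines the response without them, so
   the true `beta` is zero and fitted models estimate null covariate
   effects. This is deliberate and documented rather than "fixed".
7. The spatial adjacency is the symmetrized 4-nearest-neighbour graph of the
   coordinates (an edge if either unit ranks the other among its 4 nearest).
   Real contiguity matrices can be supplied as CSV instead.

Scenario defaults are the study conditions: `N = 54` units, `T = 20` time
points (1080 records), correlation grids `{0.05, 0.15, ..., 0.95}` in each
dimension (100 scenarios), 1000 replications per scenario at full scale, and
a 70/30 record-level train/test split for validation. Offsets default to
zero (unit exposure): the generating process has no population sizes, and
per-record exposures can be supplied from CSV when fitting real data.

What the generator does *not* emulate: real border contiguity, missing data
and imputation, covariates that actually drive the response, overdispersion
beyond the latent log-normal-like variation, and population offsets. Passing
tests therefore demonstrate correctness of the machinery and the qualitative
model ordering under the stated latent structure, not performance on any
real surveillance data.

## Sampler

The posterior is sampled on an unconstrained scale: logit for each `rho`,
log for each variance, Jacobians included. Gradients are analytic; because
`Q(W, rho)` shares eigenvectors with the graph Laplacian for every `rho`,
log-determinants and their `rho`-derivatives are O(N) after one
eigendecomposition per graph.

The core kernel is the No-U-Turn Sampler: doubling trajectory expansion with
slice sampling across the built tree, a divergence guard at energy error
1000, dual-averaging step-size adaptation toward acceptance 0.8, and a
diagonal mass matrix estimated over expanding burn-in windows (an initial
15% step-size-only phase, doubling covariance windows, and a final 10%
step-size-only phase). Momentum is refreshed from `N(0, M)` with zero mean —
the standard choice.

Two parameterizations of the random effects are available and target the
same posterior: *centered* (effects on their natural scale; the default for
fitting, and the faster of the two on fully observed panels) and
*non-centered* (`phi = sqrt(k2) * phi_raw` with unit-scale priors on
`phi_raw`), which removes the funnel between an effect block and its
variance and is the right geometry when the likelihood is weak — the prior
sampling tests use it. The centered path dispatches to compiled (numba)
kernels that mirror the numpy reference implementation; the test suite
asserts the two agree to near machine precision on random states.

A Gaussian random-walk Metropolis backend with Robbins-Monro scale
adaptation is included because it is bit-reproducible under a fixed seed,
which the orchestration tests rely on; it is never the default.

Chain profiles: `study` = 120,000 iterations, 20,000 burn-in, thin 10
(10,000 retained draws, the study configuration, preserved verbatim);
`desk` = 6,000 / 1,000 / 5 with maximum tree depth 6, used for replicated
experiments on one core; `smoke` = 1,200 / 400 / 2 for quick checks.
Retained-draw count is `floor((n_total - burn_in)/thin)`. Initial states:
`beta` from a least-squares fit of `log(y + 0.5) - offset` on the
covariates, effects at zero, `rho` at 0.5 and variances at 0.1, all jittered
until the log posterior is finite. One chain is run by default (split-chain
R-hat is reported from the halves); multiple chains are supported for
proper potential-scale-reduction diagnostics.

## Evaluation

- `WAIC = -2 (lpd - pWAIC)` with `lpd = sum_i log mean_s p(y_i | theta_s)`
  computed by log-sum-exp, and `pWAIC = sum_i Var_s[log p(y_i | theta_s)]`
  using the sample variance (denominator S-1). The variance-based
  (second-form) effective-parameter estimator is the printed formula.
- RMSE and MAE follow the standard definitions (root mean squared error,
  mean absolute error) of the posterior-mean fitted intensities against the
  observed counts.
- Coverage: the model is fitted with test records masked out of the
  likelihood; their cell-level random effects are then constrained only by
  their priors, so posterior draws of those effects are prior draws given
  the sampled hyperparameters. For each test record and each retained draw
  a zero-truncated Poisson count is simulated (truncation matches the
  support of the generating process); equal-tailed 2.5/97.5 percentiles form
  the interval, and coverage is the percentage of observed test counts
  inside. Intervals for the latent intensity (credible rather than
  predictive) are available behind a flag.

## Experiment orchestration and problem sizes

Per-replication seeds derive from `(base_seed, sp, tm, replication)` through
a `SeedSequence`, so any scenario is reproducible in isolation. Replication
rows stream to a tidy CSV; interrupted grids resume by skipping completed
(scenario, replication, model) rows. Failed fits are flagged, excluded from
aggregates, and counted. Models are ranked per scenario by mean WAIC with
ties broken by mean RMSE then model name.

Replicated studies in this repository run at reduced scale, chosen so the
full suite completes on a single core while Monte-Carlo error stays well
below the effect sizes being tested: the model-comparison and validation
grids use `sp, tm in {0.05, 0.5, 0.95}` (the corners and centre of the study
grid), 5 replications per scenario, panels of 15 x 8 (tests) or 20 x 10 (the
acceptance script), and the desk chain profile. Parameter-recovery runs use
20 seeded datasets per model at 15 x 8 with 3 covariates. The full-scale
design (100 scenarios x 1000 replications x 4 models at the study profile)
is expressible with the same `ExperimentConfig` and is intended for cluster
execution.

## Known limitations

- The four models are fitted with a single chain by default; multimodality
  would go undetected without explicitly requesting multiple chains.
- WAIC is computed on the training panel (all records for comparison runs),
  not on held-out data; coverage is the only out-of-sample metric.
- The inverse-gamma default is weakly informative but not flat; variance
  posteriors at very small effect scales are prior-sensitive, as usual for
  CAR variance components.
- The non-centered parameterization is not the default for fitting; on very
  sparse or mostly masked panels it may mix better and should be selected
  manually (`build_model(..., centered=False)`).
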