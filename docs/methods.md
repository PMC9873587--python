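# Methods

## The model

The package fits a community (multi-species) site-occupancy model to
repeat-visit detection/nondetection data from insect traps. For species
*i*, site *j*, visit *k*:

    x_ijk ~ Bernoulli(p_jk · z_ij)
    z_ij  ~ Bernoulli(ψ_ij)

    logit(ψ_ij) = ψ0 + a_i + ψ_Burn·Burn_j + ψ_Canopy·Canopy_j
                  + ψ_Burn×Canopy·Burn_j·Canopy_j
                  + ψ_FA·logFA_j + ψ_FR·FR_j

    logit(p_jk) = p0 + p_Burn·Burn_j + p_Canopy·Canopy_j
                  + p_FA·logFA_jk + p_FR·FR_jk
                  + p_Hours·Hours_jk + p_Day·Day_jk

`z_ij` is the latent true presence of species *i* at site *j*; a species
is detectable only where present. Occupancy covariates are site level
(burn status 0/1, canopy openness as a fraction of open sky, site-level
floral abundance and richness); detection covariates are site or visit
level (floral counts at the visit, trap hours, Julian day). The species
random intercept `a_i ~ Normal(0, σ)` lets species differ in overall
occupancy while sharing covariate effects — appropriate for a small,
skewed dataset where species-specific slopes are not estimable. Detection
probability is shared across species: with passive traps active for
hundreds of hours per visit, a single individual entering the trap
records the species, so per-species detectability differences are assumed
second-order (and are not identifiable at this data size anyway).

### Assumptions

- Closure: `z_ij` is constant across the season's visits.
- No false positives: detections only where `z_ij = 1`.
- Visits are conditionally independent given `z` and the covariates.
- Species are exchangeable around the community intercept; covariate
  effects are community level.

## Covariate preprocessing

- Floral abundance is transformed `log(x + 1)` before use; unburned
  forest sites can have zero open flowers, so a plain log is undefined.
  The offset is fixed at 1 flower.
- Site-level floral covariates (occupancy side) are the mean over that
  site's visits of the visit-level values, taken after the log transform
  for abundance. A pooled-sum alternative is available
  (`build_design(..., site_floral_aggregation="pooled_sum")`).
- Continuous covariates are z-scored (mean 0, sd 1, ddof = 1): site-level
  covariates over sites, visit-level covariates over observed visits.
  Burn status stays 0/1. Each column's (mean, sd, transform) is recorded
  so effect curves report original units.
- Canopy openness is stored as a fraction in [0, 1]; percent-scale input
  (any value > 1) is divided by 100 at read time.
- Detections are site-visit level: the multiple traps at a site pool into
  one binary record per species per visit, since the detection model has
  no trap index.

## Priors

The fixed effects (intercepts and coefficients) get `Normal(0, 10)`
priors; the species-effect scale gets `σ ~ Uniform(0, 10)`. Both are
weakly informative on the logit scale and conventional for this model
class; both are configurable (`PriorSpec`). With only ~26 sites the
occupancy-side posterior remains wide and prior tails matter for the
intercept — summaries on the probability scale (stratum occupancy) are
much more stable than raw logit-scale coefficients.

## Samplers

Two independent MCMC implementations target the same posterior and are
required (by the test suite) to agree within Monte-Carlo error:

- **Data-augmented** (default): alternates (a) exact Gibbs draws of every
  `z_ij` from its full conditional — any detection forces `z = 1`,
  otherwise `P(z=1 | x=0) = ψ·Π(1−p) / (ψ·Π(1−p) + 1 − ψ)` — with
  (b) random-walk Metropolis updates of each scalar parameter against the
  complete-data posterior (species effects updated as an independent
  vector of per-species proposals) and (c) a log-scale Metropolis step
  for σ.
- **Marginalized**: sums `z` out analytically per detection history
  (`ψ·Π p^x (1−p)^(1−x) + (1−ψ)·1[history all zero]`) and runs scalar
  Metropolis on the marginal posterior. Slower per sweep but free of
  latent variables; it doubles as the reference for the augmented path.

Proposal scales adapt toward a 0.44 acceptance rate during burn-in only
(Robbins-Monro batches of 50) and are frozen afterwards, so retained
draws come from a fixed-kernel Markov chain. Chains are initialized
independently: location parameters from `Normal(0, 2.5)` and
`σ ~ Uniform(0.25, 4)`. This is overdispersed relative to the posterior —
which is what the Gelman-Rubin diagnostic needs — without starting at
logits of ±20–30 where a random walk stalls for a long time; drawing
initials from the full `Normal(0, 10)` prior does the latter. Per-chain
seeds derive deterministically from the master seed
(`numpy.random.SeedSequence.spawn`), so runs are exactly reproducible.

Species deviations are identified through their hierarchical prior, not
by a sum-to-zero constraint: an in-sampler recentering sweep is a
deterministic move that does not leave the posterior invariant and would
also break the augmented-vs-marginalized agreement check. For reporting,
`center_species_effects` re-expresses retained draws with mean-zero
deviations (the intercept absorbs the mean), leaving every
probability-scale quantity unchanged.

Default chain settings are desk scale (3 chains × 20,000 iterations,
5,000 burn-in, thin 10). `MCMCConfig.paper_settings()` gives the full
protocol (3 × 1,000,000, burn-in 100,000, thin 1000). Whether the
iteration count includes burn-in is convention-dependent;
`iterations_include_burnin` exposes both readings (default: included).

## Diagnostics and summaries

- **Gelman-Rubin**: the classic potential scale reduction factor
  `sqrt(((n−1)/n·W + B/n)/W)` (not the rank-normalized split variant),
  matching the default of the general-purpose Gibbs engines of the era
  this model class comes from; < 1.1 is the conventional convergence rule.
- **Summaries**: pooled-chain mean, equal-tailed 95% credible interval
  from empirical quantiles with linear interpolation, and an
  excludes-zero flag (the usual boldface criterion in occupancy tables).
- **Stratum occupancy**: per retained draw, ψ_ij is averaged over every
  (species, site) pair in a burn stratum; the posterior of that average
  is the community-mean occupancy of the stratum. Averaging over species
  (rather than reporting a "typical species") matches the community-level
  framing the single shared set of covariate effects implies.
- **Monte-Carlo SEs** for cross-sampler comparisons use
  sd/√ESS with arviz effective sample sizes.

## Synthetic surveys

`ScenarioConfig()` defaults emulate the targeted study design: 26 sites
(half burned), 2 visits per site, 10 species, and burned-minus-unburned
mean shifts of +0.40 in canopy fraction, +120 open flowers and +5
flowering species. Generating distributions are package choices (the
field data report only the observed contrasts): canopy ~ Beta with
stratum mean and concentration 20; open-flower counts ~ negative binomial
(dispersion 2); richness ~ Poisson; trap hours ~ Uniform(281, 508), the
observed range; visit-1 Julian day uniform in mid-June, revisit 28–42
days later. Detection histories are then drawn from the occupancy model
itself, so generator and likelihood share one definition of the process.

What the generator does *not* emulate: spatial correlation between sites,
within-season flowering phenology, abundance-dependent detectability, and
misidentification. Passing recovery tests therefore demonstrate sampler
and likelihood correctness under the model's own assumptions, not
robustness to their violation in field data.

### Recovery scenario

Parameter-recovery experiments (`recovery_scenario()`: 200 sites, 4
visits, 15 species, true burn effect +2) draw covariates with **zero**
burned/unburned mean shift, so burn status is near-orthogonal to the
other covariates and every coefficient is well identified — the standard
design for checking sampler calibration. Under the study-like confounded
defaults, burn status and standardized canopy are nearly collinear
(r ≈ 0.9, plus the interaction column), the burn coefficient's posterior
sd grows several-fold, and its posterior mean scatters accordingly for
any correct sampler; that scatter measures the design, not the sampler.
Measured at these settings: ~91% coverage of nominal 95% intervals across
fixed effects and mean absolute burn-coefficient deviation ≈ 0.1.

## Numerical choices

- Logit-scale likelihood algebra uses `z·η − log(1+e^η)` via
  `numpy.logaddexp` throughout; no probability is formed where an
  underflow could bite, except the final marginal per-history likelihood,
  which is floored at 0 and yields −∞ log-likelihood (a rejected proposal)
  in the astronomically unlikely exact-zero case.
- Standardization refuses zero-variance columns (sd ≤ 1e-12).
- Quantiles: `numpy.quantile` default linear interpolation.
- Acceptance rates outside [0.05, 0.95] after adaptation produce a
  warning, never an error; degenerate data can legitimately pin a
  parameter.

## Problem sizes

Test and script runs use scaled-down chains chosen as the smallest sizes
at which the checks are statistically meaningful: sampler agreement on a
5-species × 20-site × 2-visit survey with 3 chains × 12,000 iterations;
recovery over 20 replicates (10 in the acceptance script) with 2 chains ×
5,000 iterations each; enumeration checks on ≤ 3 × 4 × 3 instances where
the 2^(S·J) brute force is exact. The full-protocol configuration is
provided for analyses of real surveys.

## Known limitations

- Random-walk Metropolis mixes slowly for strongly correlated posteriors
  (e.g. ψ0 vs species deviations at few sites); the full protocol's long
  chains compensate, as do probability-scale summaries.
- No species-specific detection effects, spatial random effects, or
  N-mixture (abundance) extensions.
- The 26-site default scenario is intentionally weakly identified — as in
  the real survey — so logit-scale coefficient estimates from it carry
  wide intervals; tests assert calibration at the 200-site recovery scale
  instead.
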