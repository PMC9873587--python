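# bombus-occupancy

Hierarchical multi-species occupancy modelling for bumble-bee (*Bombus*)
trap surveys across burned and unburned forest.

## The problem

Passive trap surveys confound two very different questions: *is a species
there?* and *would we catch it if it were?* Habitat features — open
canopy, flower abundance and diversity — plausibly affect both. A
community occupancy model separates them: for species *i*, site *j*,
visit *k*,

    x_ijk ~ Bernoulli(p_jk · z_ij)        detection given presence
    z_ij  ~ Bernoulli(ψ_ij)               latent occupancy

with logit-linear covariates on occupancy ψ (burn status, canopy
openness, their interaction, site-level log floral abundance, floral
richness) and on detection p (burn status, canopy, visit-level floral
covariates, trap hours, Julian day), plus a species random intercept
a_i ~ Normal(0, σ) on occupancy. Fitting is by MCMC — a data-augmented
Metropolis-within-Gibbs sampler, cross-checked against an independent
marginalized-likelihood sampler — with classic Gelman-Rubin convergence
diagnostics and equal-tailed 95% credible intervals.

The package is for ecologists analysing repeat-visit
detection/nondetection data of a small pollinator community, and includes
a synthetic-survey generator emulating a 26-site burned/unburned design
so every stage is testable without field data. See `docs/methods.md` for
the full model account.

## Worked example

```bash
python analysis/02_simulate_survey.py    # 26 sites, 2 visits, 10 species
python analysis/03_fit_occupancy_model.py
```

The fit (3 chains × 20,000 iterations, desk scale) prints the posterior
summary and stratum occupancy:

```
                      parameter  mean  bci_low  bci_high  excludes_zero  rhat
                           psi0  0.42    -2.39      3.55          False  1.06
                psi_burn_status  3.06    -0.38      8.09          False  1.05
            ...
              p_canopy_openness  0.86     0.08      1.59           True  1.00
              p_floral_richness -1.20    -1.73     -0.72           True  1.00
                   p_julian_day  0.99     0.64      1.39           True  1.00

max rhat 1.062 (converged at the < 1.1 rule)
burned community-mean occupancy: 0.85 (95% BCI 0.75-0.94)
unburned community-mean occupancy: 0.50 (95% BCI 0.35-0.76)
```

Read: on this synthetic survey (true burn effect +2 on the logit scale),
community-mean occupancy is credibly higher at burned sites, while
detection probability rises with canopy openness and Julian day and falls
with floral richness — traps compete with flowers for bees. Logit-scale
occupancy coefficients carry wide intervals at 26 sites; the
probability-scale stratum summary is the stable quantity. The remaining
drivers (`analysis/01...06`) cover capture tallies, posterior effect
curves, covariate-subset robustness sweeps and species-accumulation
curves; a `bombus-occ` CLI (`simulate`/`fit`/`summarize`/`curves`/
`accumulate`) wraps the same library for shell use.

To fit real data, point `bombus-occ fit` at `sites.csv`
(site_id, burn_status, canopy_openness), `visits.csv` (site_id,
visit_index, floral_abundance, floral_richness, trap_hours, julian_day)
and `detections.csv` (site_id, visit_index, species, detected), and use
`MCMCConfig.paper_settings()` — 3 chains × 1,000,000 iterations, 100,000
burn-in, thinning 1000 — for production runs.

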