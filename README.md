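# seabirdipm

Bayesian age-structured state-space population modelling for seabird
colony time series, with stochastic search variable selection (SSVS)
over candidate demographic covariates.

## The problem

Long-term colony monitoring of a declining seabird — the motivating
system is a Macaroni Penguin (*Eudyptes chrysolophus*) colony censused
annually for 28 breeding seasons — typically yields three partially
overlapping data streams:

* annual counts of breeding pairs and of chicks fledged (with repeated
  within-season censuses in some years),
* mark-recapture survival estimates with 95% CIs for two age classes,
  available only for a late sub-window of the series,
* candidate covariate series (a predation-pressure index, sea-surface
  temperature anomalies, climate indices with lags, female arrival
  mass, inter- and intraspecific competition proxies), several with
  long missing segments.

The scientific question is which *top-down* (predation) and
*bottom-up* (food-related) drivers act on which demographic rate, and
how strongly each shapes the population trajectory.  `seabirdipm`
answers it inside a single estimation framework: an integrated
population model in which every covariate competes for inclusion while
measurement error, demographic stochasticity and missing data are all
propagated.

## The model

The female population is divided into six stages (ages 1–5 and
breeding adults, a 1:1 sex ratio assumed).  The deterministic
projection is the Leslie-type matrix

```
        ⎡ 0    0    0    0    0   φa (b/2) φf ⎤
        ⎢ φa   0    0    0    0       0       ⎥
  R_t = ⎢ 0    φa   0    0    0       0       ⎥
        ⎢ 0    0    φa   0    0       0       ⎥
        ⎢ 0    0    0    φa   0       0       ⎥
        ⎣ 0    0    0    0    φa      φa      ⎦
```

realised stochastically through binomial draws at the individual
level.  The vital rates follow logit-linear covariate models with
Bernoulli inclusion indicators `I_k`, `J_k` (uniform priors on their
inclusion probabilities):

```
logit(φf,t) = αf0 + (I1 α1 + I2 α2) P_t + I3 α3 S_{t-1}
logit(φa,t) = αa0 +  I1 α1        P_t + I3 α3 S_{t-1}
logit(b_t)  = β0 + J1 β1 A_t + J2 β2 P_t + J3 β3 S_t + J4 β4 S_{t-1}
            + J5 β5 M_t + J6 β6 M_{t-1} + J7 β7 E_{t-2} + J8 β8 E_{t-3}
            + J9 β9 D_t + J10 β10 C_t
```

where `C_t` is the model's own latent breeding-female count fed back
as a density-dependence auto-covariate.  Counts are observed through a
normal error with variance `s² = σ̄²/n̄` estimated from the repeated
censuses; survival estimates through a normal error whose variance is
uniform below a gamma-distributed maximum matched to the published
CIs.  Missing arrival-mass years are imputed i.i.d. normal; the
missing early predation block follows a backward random walk anchored
at the first observed year.  Inference is by a purpose-built
Metropolis-within-Gibbs sampler (Kuo–Mallick style indicator updates);
convergence is monitored with the Brooks–Gelman–Rubin statistic.

Downstream analyses: a broken-stick (one-breakpoint segmented)
regression splits the trajectory into decline/stability periods;
"validation without data" re-simulates the series from independently
resampled marginal posteriors; a 5000-pair bootstrap of squared
trajectory residuals ranks covariates by their influence on the
population trajectory.

## Worked example

Everything runs from synthetic data generated by the package itself
(the generator mirrors the study design: a steep decline that
stabilises, survival data for the last 8 seasons, predation missing
before the 2001-analogue, arrival mass before the 1989-analogue):

```bash
seabirdipm simulate --scenario paper_like --out runs/sim
seabirdipm fit --counts runs/sim/counts.csv \
               --covariates runs/sim/covariates.csv \
               --survival runs/sim/survival.csv \
               --set mcmc.seed=1 --out runs/fit
seabirdipm report --fit-dir runs/fit --out runs/report
seabirdipm changepoint --counts runs/sim/counts.csv --out runs/trend
```

`changepoint` prints, for the packaged fixture:

```
breakpoint 2000.7 (SE 0.77); rates -9.03%/yr then -1.73%/yr
```

i.e. the breeding population fell by ~9% per year until the
2001-analogue season and was roughly stable afterwards.  `report`
prints the maximum Gelman–Rubin statistic over the monitored
parameters (values below 1.02 indicate the three chains mixed) and
writes `inclusion_probabilities.csv`; in the fixture fit the terms
that truly drive the data (shared predation on survival, arrival mass,
ENSO lag-3 and density dependence on productivity) carry posterior
inclusion probabilities near 1, while null terms stay far below 0.5.

The same pipeline is available as a library (`generate_dataset`,
`StateSpaceModel`, `run_mcmc`, `fit_broken_stick`,
`covariate_sensitivity`, `validate_without_data`, ...); see
`docs/methods.md` for the modelling details and design choices.

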