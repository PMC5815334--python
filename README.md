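# ipwmort

Mortality rates and life expectancy from census-linked survey samples are
biased when participation is **informative**: people in poor health respond
to surveys less often *and* die sooner, so the effective sample is healthier
than the population it is weighted to represent. Calibrated survey (CS)
weights — built from selection and response probabilities on observed
covariates — fix cross-sectional margins but not survival outcomes, because
the latent health that drives nonresponse never enters them.

`ipwmort` is an analysis package for quantifying and correcting this bias.
It provides:

- a **population simulator** with the causal structure *age/gender → latent
  health → {nonresponse, survival}*: constant-hazard survival with hazard
  ratio 4 for poor health, logistic nonresponse with odds ratio 4, both
  calibrated to target marginal rates;
- **survey sampling and weighting**: planned random sampling, health-driven
  nonresponse, CS weights `1 / (f · p̂_resp(x))`, and **inverse-probability
  (IP) weights** `1 / p̂(in effective sample | x, survival information)` from
  a logistic participation model fitted on the full population that includes
  the vital-status indicator, the Nelson–Aalen cumulative hazard
  `H(t) = Σ_{t_j ≤ t} d_j / n_j` evaluated at each individual's exit time,
  and age/gender × survival interactions;
- **estimators**: weighted Poisson mortality rates (closed form
  `Σ w·d / Σ w·t` per stratum, sandwich CIs), weighted covariate marginals,
  and exact crude participation odds ratios from count tables;
- a **weighted censored skew-normal** engine, `SN(ξ, ω, α)` fitted by
  maximum likelihood under right censoring and left truncation (delayed
  entry), with remaining life expectancy `LE(a) = ∫ₐ S(t)dt / S(a)`;
- a **Monte Carlo harness** crossing death fraction {10%, 25%}, sampling
  fraction {1%, 10%} and nonresponse {10%, 25%}, summarized as bivariate
  population-vs-sample log-rate centres with 95% Gaussian confidence
  ellipses.

## Worked example

Crude participation odds ratios from the packaged published count table:

```bash
python analysis/01_participation_odds.py
```

```
Vital status: OR 0.67 (0.64-0.70) — the deceased were substantially less
likely to have been survey participants.
```

The simulation study (`python analysis/02_simulation_bias.py`) reports the
mean log mortality-rate bias per scenario and scheme; in the 25% deaths /
10% sampling / 25% nonresponse scenario the unweighted and CS-weighted log
rates run about 0.11 log units below the population truth while the
IP-weighted estimate is indistinguishable from zero bias.

Life expectancy under each weighting scheme (synthetic census by default;
drop the anonymized `SwissCensus2010.csv` into `data/` to analyse the real
linkage):

```bash
python analysis/03_life_expectancy.py
```

```
Men: population 40.3 y, CS-weighted 46.1 y (bias +5.8), IP-weighted 42.0 y (bias +1.7)
Women: population 39.4 y, CS-weighted 41.1 y (bias +1.7), IP-weighted 38.9 y (bias -0.5)
```

CS weighting overestimates life expectancy because the dead are
under-represented among participants; IP weighting, which conditions on
survival information, lands near the population value.

There is also a CLI (`ipwmort simulate|grid|weights|rates|le|or-table`) for
running the same steps from a shell; see `ipwmort --help`.

## Layout

- `src/ipwmort/` — the library (every computation lives here);
- `analysis/` — numbered narrative drivers writing tables to `results/`;
- `tests/` — unit, property and end-to-end acceptance tests;
- `docs/methods.md` — model assumptions, parameter choices, numerics and
  limitations.
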