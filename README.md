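# longsig

Longitudinal pharmacovigilance toolkit: patient-month disproportionality
signal detection with Bayesian shrinkage and protopathic-bias filtering,
inverse-probability-of-treatment weighting for time-varying confounding,
marginal-structural cohort analyses, and a synthetic cohort generator with
plantable ground truth for estimator-recovery testing.

## What it does

Follow-up is discretised into fixed 30-day months per participant; each
patient-month is classified by drug exposure (three attribution windows:
current/previous month, preceding six months, ever) and by incident
adverse event occurrence. On top of that unit of observation:

* **`panel`** — domain model and panel construction from raw tabular
  records; incident-event censoring; lymphopenia grading (800/500/200
  cells/mm³ boundaries), liver-function classes (>2.5×/>5× ULN), EDSS
  progression detection.
* **`disprop`** — 2×2 patient-month contingency tables and the ROR, PRR,
  RRR and IRR with log-scale (Woolf/sandwich) confidence intervals, crude
  or weighted. The PRR and IRR coincide exactly in this formulation; both
  computation routes are implemented and tested against each other.
* **`bcpnn`** — conjugate Bayesian shrinkage of the information component
  (log2 RRR) with posterior null probability per signal (the FDR
  statistic) via seeded Monte Carlo.
* **`leopard`** — protopathic-bias filter: one-sided binomial test of
  treatment initiations before vs after incident events, carried out at
  the 50% level; rejected signals are discarded.
* **`weights`** — episode propensity weights and stabilized time-varying
  IPTW over 6-month intervals (pooled multinomial logistic assignment
  models, cumulative-ratio weights, percentile truncation, positivity and
  balance diagnostics).
* **`cohort`** — new-user cohort analyses: stratified exposed/unexposed
  episode analysis, marginal-structural models with four exposure
  parameterisations (current class, carryover, cumulative, decayed
  cumulative), switch-interaction extension; pooled log-linear fits with
  cluster-robust variance or time-varying Cox.
* **`pipeline`** — the three-level signal procedure (minimum-report list
  at 3/5/2 participants; lower-95%-bound > 1 screen; FDR < 5% + LEOPARD
  screen) across crude / subgrouped / weighted pathways, pooled ranked
  lists, drug-drug-event scans, pediatric and interim analyses.
* **`simulate`** — discrete-time cohort generator: AR(1) disease severity,
  confounded multinomial treatment assignment with switching, Bernoulli
  event hazards with configurable true rate ratios, and a protopathic
  scenario where event hazard spikes just before treatment initiation.
  Presets: `null`, `planted_signal`, `confounded`, `protopathic`,
  `switching_carryover`.

## CLI

```sh
longsig simulate --preset confounded --n 4000 --months 60 --seed 1 --out data/
longsig signals  --data data/ --exposure-def E1 --pathways crude,subgroup,weighted --out out/
longsig interim  --data data/ --out out/
longsig cohort   --data data/ --outcome INFECTION --model B --out out/
```

Input files are plain CSV with ISO-8601 dates (`participants.csv`,
`exposures.csv`, `events.csv`, `labs.csv`, optional `monthly.csv` for
time-varying covariates); see `longsig.io` for the schemas.

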