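# hdpslib

High-dimensional propensity score (HDPS) workflows for healthcare-database
cohort studies: data-driven generation and prioritisation of proxy
confounder covariates from longitudinal code records, propensity-score
weighting, and treatment-effect estimation with diagnostics.

## Who this is for

Pharmacoepidemiologists and biostatisticians analysing routinely collected
clinical or claims data (diagnosis, prescription, laboratory codes) who
want empirical confounder selection alongside investigator-specified
covariates — and a fully synthetic test bed, since the real cohorts such
analyses run on are typically restricted.

## The method

Codes are split into data dimensions (`dx`, `rx`, `lab`), restricted to a
covariate-assessment window before each patient's index date, and
aggregated (e.g. ICD-9 three-digit roots). Each candidate code expands
into up to three binary recurrence covariates (recorded ≥ 1, ≥ median,
≥ upper-quartile times). Every covariate C is then scored by the Bross
bias formula

```
bias(C) = [ pc1·(RR_CD − 1) + 1 ] / [ pc0·(RR_CD − 1) + 1 ]
```

where `pc1`, `pc0` are C's prevalence among exposed/unexposed and `RR_CD`
its crude outcome risk ratio (inverted when < 1 so magnitude drives the
ranking; 2×2 tables containing a zero get 0.1 added to all four cells).
Covariates are ranked by `|ln bias|`; the top N (default 250) join the
predefined covariates in a logistic propensity-score model. Effects are
estimated by stabilised inverse-probability-of-treatment weights, trimmed
by capping at the 99th percentile, in a weighted Cox model with robust
variance. Diagnostics cover absolute standardised differences (< 0.10 =
well-balanced), PS overlap, Bross-bias distributions, and an
exposure-vs-outcome association map flagging empirically IV-like
covariates (|ln RR_CE| > 1.5 and |ln RR_CD| < 0.5).

## Worked example

```python
from hdpslib import HdpsSettings, SimulationScenario, run_hdps, simulate

sim = simulate(SimulationScenario(n_patients=2000, seed=42))
res = run_hdps(sim.dimensions, sim.master, HdpsSettings(n_select=50))
print(res.estimates[["model", "hr", "ci_lower", "ci_upper"]])
```

prints

```
     model        hr  ci_lower  ci_upper
     crude  1.267326  1.074985  1.494080
predefined  1.190848  1.008944  1.405547
      hdps  1.017413  0.854268  1.211715
```

The cohort has a *true* hazard ratio of 1.0 and a latent frailty-like
confounder proxied by 30 codes: the crude estimate (HR 1.27) and the
predefined-covariate estimate (HR 1.19) are biased upward, while adding
the top-50 HDPS covariates to the weights returns the estimate to the
null (HR 1.02). `res.balance_summary` shows the covariates with ASD ≥
0.10 dropping from 51 (unweighted) to 0 (HDPS-weighted).

The `examples/` directory has one short script per capability (simulation,
candidate/recurrence generation, Bross prioritisation, weighting + Cox,
diagnostics, top-N sensitivity sweep). A thin CLI mirrors the pipeline
(`hdps simulate`, `hdps identify`, `hdps run-all --config config.yaml`,
`hdps sweep`); see `hdps --help`.

## Limitations

Two-arm comparisons with weighting only; no terminology services beyond
truncation/mapping tables; the synthetic generator emulates claims-like
structure, not any specific health system's coding distributions. See
`docs/methods.md` for the full model description and design rationale.
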