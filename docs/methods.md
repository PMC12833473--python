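# Methods

## The problem

In healthcare-database cohort studies the investigator can only adjust for
the confounders they thought to measure. The high-dimensional propensity
score (HDPS) approach turns the thousands of routinely recorded diagnosis,
prescription and laboratory codes into candidate *proxy* covariates for
unmeasured patient characteristics (frailty, severity, health-seeking
behaviour), ranks them by confounding potential, and adds the top-ranked
ones to the propensity-score model. `hdpslib` implements that procedure as
a seven-stage pipeline plus diagnostics and a synthetic-data generator.

## Pipeline stages and their assumptions

1. **Dimensions and windows.** Codes are organised in long format per data
   dimension (diagnoses `dx`, prescriptions `rx`, laboratory `lab`). Each
   dimension has a covariate-assessment window relative to the patient's
   index date; defaults follow common practice (entire prior history for
   diagnoses, 90 days for prescriptions, 365 days for laboratory tests).
   The window is half-open, `[index − L, index)`: baseline information must
   strictly precede treatment initiation, so index-date records are
   excluded. Patients present in a dimension but not in the master sheet
   are dropped (the master defines the cohort) with a logged tally.
2. **Candidate identification.** Diagnosis codes are truncated to their
   3-digit root by default (configurable; mapping tables are supported for
   other coding systems). Candidates are ranked by prevalence; by default
   *no* prevalence filter is applied (`n_candidates=None`,
   `min_patients=1`) — the filter's utility is debated and the default
   keeps every observed code. Prevalence ties break lexicographically on
   feature id for cross-platform determinism. Investigator-supplied
   exclusion patterns remove hand-identified exposure/outcome proxies; no
   automatic proxy detection is attempted.
3. **Recurrence assessment.** Each feature expands into up to three binary
   covariates: recorded ≥ 1, ≥ median, and ≥ upper-quartile times
   in-window. Quantiles use the nearest-rank method over the counts of
   patients *with* the code (the full-cohort median would usually be 0 and
   collapse all cutoffs), so every cutoff is an attainable integer count.
   Covariates with identical cutoffs are deduplicated (keeping the first
   suffix in once → sporadic → frequent order): perfectly collinear
   duplicates destabilise the PS fit and waste top-N budget.
4. **Prioritisation.** For each covariate the exposure and outcome 2×2
   tables are cross-tabulated over the full cohort; the covariate–outcome
   risk ratio is the crude cohort-wide ratio. If any cell of a table is 0,
   0.1 is added to all four cells of that table (each table independently),
   so every covariate receives a finite score. The Bross multiplier
   `[pc1·(rr−1)+1] / [pc0·(rr−1)+1]` is computed with rr replaced by 1/rr
   when rr < 1 (otherwise protective covariate–outcome associations would
   be systematically down-ranked; the inversion is a documented switch,
   `invert_protective`). Ranking is by `abs_log_bias` descending with
   lexicographic tie-breaks.
5. **Selection.** The top N ranked covariates (default 250) join the
   predefined covariates. Covariates flagged as empirically IV-like —
   |ln rr_ce| > 1.5 and |ln rr_cd| < 0.5, strict inequalities — can be
   removed before selection (`remove_iv_like`), the standard sensitivity
   analysis against Z-bias.
6. **PS estimation.** Logistic regression (statsmodels GLM-Binomial) of
   exposure on predefined + selected covariates; constant columns are
   dropped with a warning. Sparse binary covariates make quasi-separation
   likely, so a failed fit falls back to a weakly ridge-penalised logistic
   regression (scikit-learn, C = 100) with the fallback logged.
7. **Weighting and outcome model.** Stabilised weights `p̄/ps` (exposed)
   and `(1−p̄)/(1−ps)` (unexposed) are trimmed by *capping* at the 99th
   percentile of the pooled weight distribution (linear-interpolation
   percentile). Capping rather than excluding keeps the estimand's
   population intact while still limiting variance; this is a deliberate
   reading of "trimmed at the 99th percentile", which is ambiguous between
   the two. The hazard ratio comes from a weighted Cox partial-likelihood
   fit of outcome on exposure alone (lifelines) with a robust sandwich
   variance, since weighting induces dependence the model-based variance
   ignores. PS values at the numerical boundary are clipped to
   [1e−6, 1−1e−6].

## Diagnostics

Absolute standardised differences use the binary form
`|p1−p0| / sqrt((p1(1−p1)+p0(1−p0))/2)` and the pooled-variance form for
continuous covariates; ASD < 0.10 is labelled well-balanced. Balance is
reported per covariate under three schemes (unweighted, predefined-only
weights, HDPS weights) with group labels splitting HDPS covariates at rank
150 (configurable), since lower-ranked covariates tend to stay less well
balanced. PS overlap summaries report per-arm deciles, the common-support
range `[max of minima, min of maxima]`, and shared-bin histograms. The
association map exports (ln rr_ce, ln rr_cd) per covariate with robust
z-score outlier flags (median/MAD, threshold 3.5) and the IV-like flag.

## Synthetic-data generator

Real hospital-authority cohorts are restricted, so validation runs on
synthetic cohorts with known ground truth. A latent binary confounder U
(prevalence 0.3 by default) drives exposure (log-odds shift `alpha1 = 1.0`)
and outcome hazard (log-hazard shift `beta_u = 0.7`), and is *proxied* by a
subset of codes (30 of 45 by default) whose Poisson occurrence rates are
multiplied by 5 when U = 1; base rates are drawn per code from U(0.1, 0.5),
roughly 10%–40% marginal code prevalence, claims-like territory. Survival
is exponential with baseline hazard 0.05/year, administratively censored
at 5 years (≈ 25% event rate); two measured covariates (standardised age,
sex) carry small exposure and outcome effects so "predefined-only"
adjustment is meaningful but cannot remove the latent confounding. Event
dates are drawn uniformly inside each dimension's window — windowing logic
needs date variation and nothing constrains their true distribution.

What the generator does **not** emulate: real coding-frequency
distributions (heavy tails over thousands of codes), code correlation
structure beyond the single latent factor, informative censoring,
time-varying treatment, or measurement of U itself. Passing tests
therefore show the pipeline recovers confounding that is *expressible
through code proxies*; they say nothing about confounders that leave no
trace in the database.

Defaults reproduce the reference study conditions used throughout the
tests: n = 20 000 patients, 20 seeds, top 50 covariates selected. Under
the null (true HR = 1) the crude estimate is biased upward
(mean |log HR| ≈ 0.2) while the HDPS-adjusted estimate returns to ~0;
with true HR = 0.8 the adjusted estimate recovers it. The test and
acceptance problem sizes (2 000-patient fixtures for unit tests, 20 000 ×
20 seeds for end-to-end properties) were chosen as the smallest sizes at
which the Monte-Carlo error is comfortably below the property margins.

## Numerical choices and degenerate inputs

* Nearest-rank quantiles guarantee integer, attainable cutoffs; ties and
  degenerate count distributions (all counts equal) collapse to a single
  `_once` covariate rather than three identical columns.
* All ranking tie-breaks are lexicographic on covariate id — bit-identical
  output across runs and platforms.
* A covariate observed in nobody (all-zero column) yields a zero-filled
  2×2 table, which the zero-cell correction turns into a finite,
  near-null score rather than an error.
* An arm with no events, a single-valued exposure or outcome, and
  non-positive follow-up times raise explicit errors naming the problem;
  degenerate simulation scenarios are rejected with a diagnostic rather
  than silently producing unusable cohorts.
* Intercept-only PS models return exactly the marginal prevalence, making
  `n_select = 0` reduce bit-exactly to the predefined-only analysis and
  unit weights reduce bit-exactly to the unweighted Cox fit.

## Known limitations

* Two-arm comparisons only; multi-arm studies are run pairwise against a
  common reference.
* Weighting is the only PS method (no matching or stratification).
* The "prevalence closest to 0.5" candidate-ranking variant of the
  original algorithm is not implemented; candidates rank by raw prevalence.
* Whether the covariate–outcome risk ratio should be computed among the
  unexposed only (a known variant) is an open choice; the cohort-wide
  crude ratio is used uniformly.
* The ridge fallback changes the PS model's implicit prior; when it
  triggers (it is logged), weights should be inspected before relying on
  the estimate.
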