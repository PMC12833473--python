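"""Identify candidate features and expand them into recurrence covariates.

Diagnosis codes are truncated to their 3-digit root, candidate features are
ranked by prevalence, and each becomes up to three binary covariates
(recorded >= 1 / >= median / >= upper-quartile times in-window).
"""

from hdpslib import (GranularityRule, aggregate_codes, build_recurrence_matrix,
                     identify_candidates, make_fixture)

sim = make_fixture("small")
dx = aggregate_codes(sim.dimensions["dx"], GranularityRule("dx", truncate=3))

features = identify_candidates(dx, sim.master, n=None, min_patients=10)
print(f"candidate features (dx): {len(features)}")
top = features[0]
print(f"most prevalent: {top.feature_id} in {top.n_patients} patients "
      f"(prevalence {top.prevalence:.3f})")

X, covariates = build_recurrence_matrix([dx], sim.master, features)
print(f"recurrence covariates: {X.shape[1]} from {len(features)} features")
for c in covariates[:3]:
    prev = X[c.covariate_id].mean()
    print(f"  {c.covariate_id}: count >= {c.cutoff}, prevalence {prev:.3f}")
# The _once covariate's prevalence equals the feature's prevalence; the
# _sporadic/_frequent cutoffs capture recurrent, hence likely chronic, codes.
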