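"""PS estimation, stabilised trimmed weights, weighted Cox."""

import numpy as np
import pandas as pd
import pytest

from hdpslib import (CohortMaster, EffectEstimate, fit_ps, fit_weighted_cox,
                     stabilised_weights)
from hdpslib.errors import EstimationError


def _master_from(exposure, outcome, time, extra=None, predefined=()):
    n = len(exposure)
    df = pd.DataFrame({
        "patient_id": [f"p{i}" for i in range(n)],
        "exposure": exposure, "outcome": outcome, "time_to_event": time,
    })
    for k, v in (extra or {}).items():
        df[k] = v
    return CohortMaster(df, predefined=tuple(predefined))


class TestFitPs:
    def test_intercept_only_gives_marginal_prevalence(self):
        rng = np.random.default_rng(0)
        e = rng.integers(0, 2, 500)
        m = _master_from(e, rng.integers(0, 2, 500), np.ones(500))
        fit = fit_ps(m, None, [])
        assert np.allclose(fit.ps, e.mean(), atol=1e-8)

    def test_independent_covariate_approaches_null_model(self):
        rng = np.random.default_rng(1)
        n = 4000
        e = rng.integers(0, 2, n)
        m = _master_from(e, rng.integers(0, 2, n), np.ones(n),
                         extra={"x": rng.normal(size=n)}, predefined=("x",))
        fit = fit_ps(m, None, ["x"])
        assert np.allclose(fit.ps, e.mean(), atol=0.05)

    def test_constant_column_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        e = rng.integers(0, 2, 200)
        m = _master_from(e, rng.integers(0, 2, 200), np.ones(200),
                         extra={"k": np.ones(200)}, predefined=("k",))
        with pytest.warns(UserWarning, match="constant"):
            fit = fit_ps(m, None, ["k"])
        assert fit.covariates == [] and "k" in fit.dropped

    def test_recovers_known_logit_coefficients_within_3se(self):
        rng = np.random.default_rng(3)
        n = 5000
        x1 = rng.normal(size=n)
        x2 = rng.integers(0, 2, n)
        beta = {"const": -0.4, "x1": 0.8, "x2": -0.6}
        logit = beta["const"] + beta["x1"] * x1 + beta["x2"] * x2
        e = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        m = _master_from(e, rng.integers(0, 2, n), np.ones(n),
                         extra={"x1": x1, "x2": x2}, predefined=("x1", "x2"))
        fit = fit_ps(m, None, ["x1", "x2"])
        assert fit.method == "glm"
        for name, true in beta.items():
            assert abs(fit.params[name] - true) < 3 * fit.bse[name]


class TestStabilisedWeights:
    def test_formula_for_both_arms(self):
        # p̄ = 0.4 by construction: 2 exposed / 5
        ps = pd.Series([0.8, 0.5, 0.8, 0.3, 0.2])
        e = np.array([1, 1, 0, 0, 0])
        wc = stabilised_weights(ps, e, trim_percentile=100.0)
        assert wc.marginal_prevalence == pytest.approx(0.4)
        assert wc.raw_weights.iloc[0] == pytest.approx(0.4 / 0.8)  # = 0.5
        assert wc.raw_weights.iloc[2] == pytest.approx(0.6 / 0.2)  # = 3.0

    def test_cap_matches_sorted_percentile_oracle_and_binds(self):
        rng = np.random.default_rng(4)
        ps = pd.Series(rng.uniform(0.05, 0.95, 1000))
        e = rng.integers(0, 2, 1000)
        wc = stabilised_weights(ps, e, trim_percentile=99.0)
        assert wc.cap == pytest.approx(np.percentile(wc.raw_weights, 99))
        assert (wc.weights <= wc.cap + 1e-12).all()
        below = wc.raw_weights < wc.cap
        assert np.allclose(wc.weights[below], wc.raw_weights[below])

    def test_mean_stabilised_weight_near_one_per_arm(self, small_sim):
        from hdpslib import run_hdps, HdpsSettings
        res = run_hdps(small_sim.dimensions, small_sim.master,
                       HdpsSettings(n_select=50))
        e = small_sim.master.data.set_index("patient_id")["exposure"]
        raw = res.weights_hdps.raw_weights
        for arm in (0, 1):
            assert raw[e == arm].mean() == pytest.approx(1.0, abs=0.1)

    def test_boundary_ps_clipped_with_warning(self):
        ps = pd.Series([0.0, 0.5, 1.0, 0.5])
        with pytest.warns(UserWarning, match="clipped"):
            wc = stabilised_weights(ps, np.array([0, 1, 1, 0]))
        assert np.isfinite(wc.raw_weights).all()


class TestFitWeightedCox:
    def test_exchangeable_arms_give_hr_one(self):
        times = [1.0, 2.0, 3.0, 4.0] * 2
        events = [1, 1, 0, 1] * 2
        e = [1] * 4 + [0] * 4
        m = _master_from(e, events, times)
        est = fit_weighted_cox(m)
        assert est.hr == pytest.approx(1.0, abs=1e-6)

    def test_unit_weights_reproduce_unweighted_fit(self, small_sim):
        m = small_sim.master
        a = fit_weighted_cox(m, None)
        b = fit_weighted_cox(m, pd.Series(1.0, index=m.patient_ids))
        assert a.log_hr == pytest.approx(b.log_hr, abs=1e-10)

    def test_ci_brackets_hr(self, small_sim):
        est = fit_weighted_cox(small_sim.master)
        assert est.ci_lower <= est.hr <= est.ci_upper
        assert est.ci_lower > 0

    def test_no_events_in_arm_names_the_arm(self):
        m = _master_from([1, 1, 0, 0], [0, 0, 1, 1], [1.0, 2.0, 1.0, 2.0])
        with pytest.raises(EstimationError, match="exposed"):
            fit_weighted_cox(m)

    def test_recovers_known_hazard_ratio_without_confounding(self):
        # exponential survival, true HR 0.8, no confounding: the mean
        # estimate over seeds must sit near the truth
        log_hrs = []
        for seed in range(6):
            rng = np.random.default_rng(100 + seed)
            n = 6000
            e = rng.integers(0, 2, n)
            rate = 0.1 * np.exp(np.log(0.8) * e)
            t = rng.exponential(1 / rate)
            event = (t < 8.0).astype(int)
            m = _master_from(e, event, np.minimum(t, 8.0))
            log_hrs.append(fit_weighted_cox(m).log_hr)
        assert 0.75 < np.exp(np.mean(log_hrs)) < 0.85


class TestStability:
    def test_noise_covariate_barely_moves_null_estimate(self):
        # adding an exposure- and outcome-independent covariate to the PS
        # shifts the weighted log HR by < 0.02
        rng = np.random.default_rng(8)
        n = 5000
        e = rng.integers(0, 2, n)
        rate = 0.1 * np.ones(n)
        t = rng.exponential(1 / rate)
        m = _master_from(e, (t < 8).astype(int), np.minimum(t, 8.0),
                         extra={"x": rng.normal(size=n),
                                "noise": rng.normal(size=n)},
                         predefined=("x", "noise"))
        def est(covs):
            fit = fit_ps(m, None, covs)
            wc = stabilised_weights(
                fit.ps, m.data.set_index("patient_id")["exposure"])
            return fit_weighted_cox(m, wc.weights).log_hr
        assert abs(est(["x"]) - est(["x", "noise"])) < 0.02
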