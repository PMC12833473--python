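"""Propensity-score estimation, stabilised trimmed IPTW, weighted Cox.

The propensity score is fit by logistic regression of exposure on the
predefined covariates plus the selected HDPS covariates. Stabilised weights

    exposed:   w = p̄ / ps        unexposed: w = (1 - p̄) / (1 - ps)

(with p̄ the marginal exposure prevalence) are trimmed by capping at the
99th percentile of the pooled weight distribution, and the marginal hazard
ratio is estimated by a weighted Cox partial-likelihood fit of outcome on
exposure alone with a robust (sandwich) variance — the weights induce
within-subject dependence that the model-based variance ignores.

Hundreds of sparse binary covariates make quasi-separation of the logistic
model likely; on non-convergence the fit falls back to a weakly ridge-
penalised logistic regression (the penalty magnitude is logged).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort_io import CohortMaster
from .errors import EstimationError

logger = logging.getLogger(__name__)

PS_CLIP = 1e-6
DEFAULT_TRIM_PERCENTILE = 99.0
#: inverse ridge strength (sklearn C) of the fallback fit — weak penalty
RIDGE_FALLBACK_C = 100.0


@dataclass
class PSFit:
    """Fitted propensity-score model."""

    ps: pd.Series                     # fitted P(exposure=1 | X), per patient
    covariates: list[str]             # columns actually used
    dropped: list[str]                # constant columns removed pre-fit
    method: str                       # "glm" or "ridge"
    params: pd.Series | None = None   # coefficients incl. intercept (glm only)
    bse: pd.Series | None = None      # standard errors (glm only)


@dataclass
class WeightedCohort:
    """Per-patient PS and stabilised trimmed weights plus cohort metadata."""

    ps: pd.Series
    raw_weights: pd.Series            # stabilised, untrimmed
    weights: pd.Series                # capped at `cap`
    cap: float                        # trim percentile of raw weights
    marginal_prevalence: float
    trim_percentile: float = DEFAULT_TRIM_PERCENTILE


@dataclass(frozen=True)
class EffectEstimate:
    """Marginal hazard-ratio estimate with robust 95% CI."""

    log_hr: float
    se: float
    n: int
    n_events: int

    @property
    def hr(self) -> float:
        return float(np.exp(self.log_hr))

    @property
    def ci_lower(self) -> float:
        return float(np.exp(self.log_hr - 1.96 * self.se))

    @property
    def ci_upper(self) -> float:
        return float(np.exp(self.log_hr + 1.96 * self.se))


def _design(master: CohortMaster, X: pd.DataFrame | None,
            covariates: list[str]) -> pd.DataFrame:
    """Assemble the PS design matrix from master columns and/or the
    covariate matrix, aligned to master patient order."""
    pieces = []
    for name in covariates:
        if name in master.data.columns:
            pieces.append(master.data.set_index("patient_id")[name])
        elif X is not None and name in X.columns:
            pieces.append(X[name])
        else:
            raise EstimationError(f"PS covariate '{name}' found in neither the "
                                  "master nor the covariate matrix")
    if not pieces:
        return pd.DataFrame(index=master.patient_ids)
    D = pd.concat(pieces, axis=1).loc[master.patient_ids]
    D.columns = covariates
    return D.astype(float)


def fit_ps(
    master: CohortMaster,
    X: pd.DataFrame | None,
    covariates: list[str],
) -> PSFit:
    """Logistic-regression propensity score.

    ``covariates`` may name master columns (predefined) and/or columns of the
    recurrence matrix ``X``; duplicates are collapsed. Constant columns are
    dropped with a warning. An empty covariate list gives the intercept-only
    model, i.e. ps = marginal exposure prevalence for everyone.
    """
    covariates = list(dict.fromkeys(covariates))  # dedupe, keep order
    D = _design(master, X, covariates)
    if len(D.columns) and not np.isfinite(D.to_numpy()).all():
        raise EstimationError("PS design matrix contains non-finite values")
    const = [c for c in D.columns if D[c].nunique() <= 1]
    if const:
        warnings.warn(f"dropping {len(const)} constant PS covariate(s): "
                      f"{const[:5]}...", stacklevel=2)
        D = D.drop(columns=const)
    y = master.data["exposure"].to_numpy(dtype=float)
    design = sm.add_constant(D.to_numpy(dtype=float), has_constant="add")
    names = ["const"] + list(D.columns)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, design, family=sm.families.Binomial()).fit(
                maxiter=200)
        if not np.isfinite(res.params).all():
            raise EstimationError("non-finite GLM coefficients")
        ps = np.asarray(res.predict(design))
        return PSFit(
            ps=pd.Series(ps, index=master.patient_ids, name="ps"),
            covariates=list(D.columns), dropped=const, method="glm",
            params=pd.Series(res.params, index=names),
            bse=pd.Series(res.bse, index=names),
        )
    except Exception as err:  # separation / non-convergence → weak ridge
        logger.warning("GLM propensity fit failed (%s); falling back to "
                       "ridge logistic (C=%g)", err, RIDGE_FALLBACK_C)
        from sklearn.linear_model import LogisticRegression

        if D.shape[1] == 0:
            p = float(y.mean())
            return PSFit(ps=pd.Series(p, index=master.patient_ids, name="ps"),
                         covariates=[], dropped=const, method="glm")
        try:
            clf = LogisticRegression(penalty="l2", C=RIDGE_FALLBACK_C,
                                     solver="lbfgs", max_iter=2000)
            clf.fit(D.to_numpy(dtype=float), y)
            ps = clf.predict_proba(D.to_numpy(dtype=float))[:, 1]
        except Exception as err2:
            raise EstimationError(
                f"propensity model failed to converge even with ridge "
                f"fallback over covariates {list(D.columns)[:10]}...: {err2}"
            ) from err2
        return PSFit(ps=pd.Series(ps, index=master.patient_ids, name="ps"),
                     covariates=list(D.columns), dropped=const, method="ridge")


def stabilised_weights(
    ps: pd.Series,
    exposure: pd.Series | np.ndarray,
    trim_percentile: float = DEFAULT_TRIM_PERCENTILE,
) -> WeightedCohort:
    """Stabilised IPTW, trimmed by capping at the pooled percentile.

    PS values at exactly 0 or 1 are clipped to [1e-6, 1 - 1e-6] with a
    warning. The cap is the linear-interpolation ``trim_percentile`` of the
    pooled (both arms) raw stabilised weights; weights above it are set to it.
    """
    e = np.asarray(exposure, dtype=float)
    p = np.asarray(ps, dtype=float)
    if ((p <= 0) | (p >= 1)).any():
        warnings.warn("propensity scores at the boundary clipped to "
                      f"[{PS_CLIP}, {1 - PS_CLIP}]", stacklevel=2)
        p = np.clip(p, PS_CLIP, 1 - PS_CLIP)
    p_bar = float(e.mean())
    raw = np.where(e == 1, p_bar / p, (1 - p_bar) / (1 - p))
    cap = float(np.percentile(raw, trim_percentile))
    trimmed = np.minimum(raw, cap)
    idx = ps.index if isinstance(ps, pd.Series) else pd.RangeIndex(len(p))
    return WeightedCohort(
        ps=pd.Series(p, index=idx, name="ps"),
        raw_weights=pd.Series(raw, index=idx, name="raw_weight"),
        weights=pd.Series(trimmed, index=idx, name="weight"),
        cap=cap, marginal_prevalence=p_bar, trim_percentile=trim_percentile,
    )


def fit_weighted_cox(
    master: CohortMaster,
    weights: pd.Series | np.ndarray | None = None,
) -> EffectEstimate:
    """Weighted Cox fit of the outcome on exposure alone.

    ``weights=None`` gives the unweighted (crude) fit. The variance is the
    robust sandwich estimator; the 95% CI is exp(log_hr ± 1.96·se).
    """
    from lifelines import CoxPHFitter

    df = master.data
    if (df["time_to_event"] <= 0).any():
        raise EstimationError("time_to_event must be positive for Cox fitting")
    for arm, label in ((1, "exposed"), (0, "unexposed")):
        sub = df.loc[df["exposure"] == arm, "outcome"]
        if sub.sum() == 0:
            raise EstimationError(f"no events in the {label} arm; the hazard "
                                  "ratio is not estimable")
    fit_df = pd.DataFrame({
        "T": df["time_to_event"].to_numpy(dtype=float),
        "E": df["outcome"].to_numpy(dtype=float),
        "exposure": df["exposure"].to_numpy(dtype=float),
    })
    if weights is None:
        fit_df["w"] = 1.0
    else:
        w = weights.loc[master.patient_ids] if isinstance(weights, pd.Series) \
            else pd.Series(np.asarray(weights))
        fit_df["w"] = np.asarray(w, dtype=float)
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(fit_df, duration_col="T", event_col="E", weights_col="w",
                robust=True)
    log_hr = float(cph.params_["exposure"])
    se = float(cph.standard_errors_["exposure"])
    return EffectEstimate(log_hr=log_hr, se=se, n=len(fit_df),
                          n_events=int(fit_df["E"].sum()))
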