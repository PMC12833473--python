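"""Confounder prioritisation via the Bross bias formula.

Each binary recurrence covariate C is scored by the multiplicative bias it
could induce on the crude exposure–outcome risk ratio if left unadjusted.
With pc1 and pc0 the prevalence of C among the exposed and unexposed, and
rr_cd the crude covariate–outcome risk ratio, the Bross multiplier is

    bias = [pc1 * (rr_cd - 1) + 1] / [pc0 * (rr_cd - 1) + 1]

and covariates are ranked by |ln bias| (larger = higher confounding
potential). Two conventions, both on by default:

* **zero-cell correction** — if any cell of a covariate's 2x2 exposure or
  outcome table is 0, add 0.1 to all four cells of that table, so every
  covariate gets a finite score rather than being silently dropped;
* **protective inversion** — rr_cd < 1 is replaced by 1/rr_cd inside the
  formula, so protective and harmful covariate–outcome associations of the
  same magnitude rank equally.

Covariates that look empirically like instrumental variables — strongly
exposure-associated (|ln rr_ce| > 1.5) yet outcome-unassociated
(|ln rr_cd| < 0.5) — are flagged; adjusting for such variables risks
amplifying residual confounding (Z-bias) and they can optionally be removed
before selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort_io import CohortMaster
from .errors import AlignmentError

ZERO_CELL_INCREMENT = 0.1
IV_LOG_RR_CE_THRESHOLD = 1.5
IV_LOG_RR_CD_THRESHOLD = 0.5


@dataclass(frozen=True)
class AssociationTable:
    """2x2 exposure and outcome tables for one covariate.

    Exposure table: e1 = #(C=1, exposed), e0 = #(C=1, unexposed), with arm
    totals n1/n0. Outcome table: d1 = #(outcome among C=1), d0 = #(outcome
    among C=0), with group totals m1/m0. Cells are floats so the 0.1
    zero-cell correction can be represented exactly.
    """

    covariate_id: str
    e1: float
    e0: float
    n1: float
    n0: float
    d1: float
    d0: float
    m1: float
    m0: float
    corrected_exposure: bool = False
    corrected_outcome: bool = False

    @property
    def corrected(self) -> bool:
        return self.corrected_exposure or self.corrected_outcome

    @property
    def exposure_cells(self) -> tuple[float, float, float, float]:
        """(C=1 exposed, C=1 unexposed, C=0 exposed, C=0 unexposed)."""
        return (self.e1, self.e0, self.n1 - self.e1, self.n0 - self.e0)

    @property
    def outcome_cells(self) -> tuple[float, float, float, float]:
        """(event C=1, no-event C=1, event C=0, no-event C=0)."""
        return (self.d1, self.m1 - self.d1, self.d0, self.m0 - self.d0)

    @property
    def pc1(self) -> float:
        return self.e1 / self.n1

    @property
    def pc0(self) -> float:
        return self.e0 / self.n0

    @property
    def rr_ce(self) -> float:
        return self.pc1 / self.pc0

    @property
    def rr_cd(self) -> float:
        return (self.d1 / self.m1) / (self.d0 / self.m0)


def build_association_tables(
    X: pd.DataFrame, master: CohortMaster
) -> list[AssociationTable]:
    """Exact 2x2 cross-tabulations of every covariate against exposure and
    outcome over the full cohort.

    ``X`` is the patients × covariates 0/1 matrix, indexed by patient_id and
    aligned to the master (same patient set).
    """
    master_ids = set(master.patient_ids)
    matrix_ids = set(X.index)
    if master_ids != matrix_ids:
        missing = sorted(master_ids ^ matrix_ids)[:10]
        raise AlignmentError(
            f"covariate matrix and master patient sets differ, e.g. {missing}"
        )
    X = X.loc[master.patient_ids]
    exposure = master.data["exposure"].to_numpy()
    outcome = master.data["outcome"].to_numpy()
    V = X.to_numpy(dtype=float)
    n1 = float(exposure.sum())
    n0 = float(len(exposure) - n1)
    e1 = exposure @ V
    e0 = V.sum(axis=0) - e1
    m1 = V.sum(axis=0)
    m0 = len(exposure) - m1
    d1 = outcome @ V
    d0 = float(outcome.sum()) - d1
    return [
        AssociationTable(
            covariate_id=str(cid),
            e1=float(e1[j]), e0=float(e0[j]), n1=n1, n0=n0,
            d1=float(d1[j]), d0=float(d0[j]),
            m1=float(m1[j]), m0=float(m0[j]),
        )
        for j, cid in enumerate(X.columns)
    ]


def zero_cell_correct(t: AssociationTable) -> AssociationTable:
    """Add 0.1 to all four cells of any 2x2 table containing a zero.

    The exposure and outcome tables are corrected independently; tables with
    no zero cell pass through unchanged (the operation is idempotent).
    """
    out = t
    if min(t.exposure_cells) == 0:
        out = replace(
            out,
            e1=t.e1 + ZERO_CELL_INCREMENT, e0=t.e0 + ZERO_CELL_INCREMENT,
            n1=t.n1 + 2 * ZERO_CELL_INCREMENT, n0=t.n0 + 2 * ZERO_CELL_INCREMENT,
            corrected_exposure=True,
        )
    if min(t.outcome_cells) == 0:
        out = replace(
            out,
            d1=t.d1 + ZERO_CELL_INCREMENT, d0=t.d0 + ZERO_CELL_INCREMENT,
            m1=t.m1 + 2 * ZERO_CELL_INCREMENT, m0=t.m0 + 2 * ZERO_CELL_INCREMENT,
            corrected_outcome=True,
        )
    return out


def bross_bias(
    pc1: float, pc0: float, rr_cd: float, invert_protective: bool = True
) -> tuple[float, float]:
    """Bross bias multiplier and its absolute log.

    ``invert_protective`` replaces rr_cd by 1/rr_cd when rr_cd < 1 so the
    ranking reflects the magnitude of the covariate–outcome association
    regardless of direction.
    """
    if rr_cd <= 0:
        raise ValueError(f"rr_cd must be positive, got {rr_cd}")
    rr = rr_cd
    if invert_protective and rr < 1:
        rr = 1.0 / rr
    bias = (pc1 * (rr - 1.0) + 1.0) / (pc0 * (rr - 1.0) + 1.0)
    return bias, abs(math.log(bias))


def flag_iv_like(
    rr_ce: float, rr_cd: float,
    log_rr_ce_threshold: float = IV_LOG_RR_CE_THRESHOLD,
    log_rr_cd_threshold: float = IV_LOG_RR_CD_THRESHOLD,
) -> bool:
    """True iff |ln rr_ce| > 1.5 and |ln rr_cd| < 0.5 (strict)."""
    return (abs(math.log(rr_ce)) > log_rr_ce_threshold
            and abs(math.log(rr_cd)) < log_rr_cd_threshold)


def prioritise(
    tables: list[AssociationTable],
    correction: bool = True,
    invert_protective: bool = True,
) -> pd.DataFrame:
    """Score, rank and flag every covariate.

    Returns the prioritisation report, one row per covariate sorted by
    ``abs_log_bias`` descending (ties broken by covariate_id; ranks 1..K):
    covariate_id, pc1, pc0, rr_ce, rr_cd, bias_m, abs_log_bias, rank,
    iv_like, corrected.
    """
    rows = []
    for t in tables:
        if correction:
            t = zero_cell_correct(t)
        bias, alb = bross_bias(t.pc1, t.pc0, t.rr_cd, invert_protective)
        rows.append({
            "covariate_id": t.covariate_id,
            "pc1": t.pc1, "pc0": t.pc0,
            "rr_ce": t.rr_ce, "rr_cd": t.rr_cd,
            "bias_m": bias, "abs_log_bias": alb,
            "iv_like": flag_iv_like(t.rr_ce, t.rr_cd),
            "corrected": t.corrected,
        })
    report = pd.DataFrame(rows)
    if len(report) == 0:
        report = pd.DataFrame(columns=[
            "covariate_id", "pc1", "pc0", "rr_ce", "rr_cd", "bias_m",
            "abs_log_bias", "rank", "iv_like", "corrected"])
        return report
    report = report.sort_values(
        ["abs_log_bias", "covariate_id"], ascending=[False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    report["rank"] = np.arange(1, len(report) + 1)
    return report[["covariate_id", "pc1", "pc0", "rr_ce", "rr_cd", "bias_m",
                   "abs_log_bias", "rank", "iv_like", "corrected"]]


def select_top(
    prioritised: pd.DataFrame, n_select: int, remove_iv_like: bool = False
) -> list[str]:
    """Top-N covariate ids in rank order (clamped to the available K).

    ``remove_iv_like`` drops flagged covariates before taking the top N —
    the usual sensitivity analysis against Z-bias.
    """
    if n_select < 0:
        raise ValueError("n_select must be >= 0")
    report = prioritised.sort_values("rank")
    if remove_iv_like:
        report = report.loc[~report["iv_like"].astype(bool)]
    return report["covariate_id"].head(n_select).tolist()
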