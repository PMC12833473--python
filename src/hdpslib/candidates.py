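"""Candidate-feature identification (codes → candidate covariates).

Raw codes are first collapsed to the configured granularity — e.g. ICD-9
diagnoses truncated to their 3-digit root, so "434.91" and "434.11" both
become "434" — then each distinct aggregated code becomes a candidate
feature scored by its prevalence (fraction of cohort patients with at least
one in-window occurrence). An optional prevalence filter keeps the commonest
codes; investigator-listed exposure/outcome proxies are removed by pattern.
"""

from __future__ import annotations

import fnmatch
import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import pandas as pd

from .cohort_io import CohortMaster, DimensionTable
from .errors import ConfigError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GranularityRule:
    """How raw codes of one dimension collapse to analysis granularity.

    Exactly one of:

    * ``truncate`` — keep the first *n* characters (ICD-style roots);
    * ``map_table`` — explicit code → group mapping, with ``passthrough``
      deciding whether unmapped codes are kept as-is (True) or dropped and
      reported (False);
    * neither — identity.
    """

    dimension_label: str
    truncate: int | None = None
    map_table: Mapping[str, str] | None = None
    passthrough: bool = True

    def __post_init__(self) -> None:
        if self.truncate is not None and self.truncate < 1:
            raise ConfigError("truncation length must be >= 1")
        if self.truncate is not None and self.map_table is not None:
            raise ConfigError("specify truncate or map_table, not both")


@dataclass(frozen=True)
class CandidateFeature:
    """An aggregated code with its cohort prevalence."""

    feature_id: str        # e.g. "dx_434"
    dimension_label: str
    code: str              # aggregated code, e.g. "434"
    n_patients: int        # distinct patients with >= 1 in-window occurrence
    prevalence: float      # n_patients / cohort size


def aggregate_codes(dim: DimensionTable, rule: GranularityRule) -> DimensionTable:
    """Replace every code by its aggregate under ``rule``.

    Row count is unchanged except under a non-passthrough map_table, where
    unmapped rows are dropped and the distinct unmapped codes recorded in
    ``meta["unmapped_codes"]`` of the returned table.
    """
    if rule.dimension_label != dim.dimension_label:
        raise ConfigError(
            f"granularity rule is for '{rule.dimension_label}' but table is "
            f"'{dim.dimension_label}'"
        )
    rec = dim.records
    meta = dict(dim.meta)
    if rule.truncate is not None:
        codes = rec["code"].str[: rule.truncate]
        rec = rec.assign(code=codes)
    elif rule.map_table is not None:
        mapped = rec["code"].map(dict(rule.map_table))
        unmapped_mask = mapped.isna()
        if unmapped_mask.any():
            unmapped = sorted(rec.loc[unmapped_mask, "code"].unique())
            meta["unmapped_codes"] = unmapped
            logger.warning(
                "dimension '%s': %d distinct code(s) not in map_table: %s",
                dim.dimension_label, len(unmapped), unmapped[:10],
            )
            if rule.passthrough:
                mapped = mapped.where(~unmapped_mask, rec["code"])
            else:
                rec = rec.loc[~unmapped_mask]
                mapped = mapped.loc[~unmapped_mask]
        rec = rec.assign(code=mapped)
    return DimensionTable(dim.dimension_label, rec, meta=meta)


def _excluded(feature_id: str, patterns: Sequence[str]) -> bool:
    return any(fnmatch.fnmatchcase(feature_id, p) for p in patterns)


def feature_id_for(dimension_label: str, code: str) -> str:
    return f"{dimension_label}_{code}"


def identify_candidates(
    dim: DimensionTable,
    master: CohortMaster,
    n: int | None = 200,
    min_patients: int = 10,
    exclude: Sequence[str] = (),
) -> list[CandidateFeature]:
    """Identify candidate features from one (windowed, aggregated) dimension.

    Features seen in fewer than ``min_patients`` distinct cohort patients are
    removed, as are features matching any ``exclude`` pattern (literal ids or
    fnmatch-style patterns such as ``"rx_2.5*"`` — meant for hand-picked
    proxies of the exposure or the outcome). Survivors are ranked by
    prevalence descending (ties broken by feature_id) and the top ``n`` kept;
    ``n=None`` with ``min_patients=1`` disables filtering entirely.
    """
    in_cohort = dim.records["patient_id"].isin(set(master.patient_ids))
    rec = dim.records.loc[in_cohort]
    counts = rec.groupby("code")["patient_id"].nunique()
    feats = [
        CandidateFeature(
            feature_id=feature_id_for(dim.dimension_label, code),
            dimension_label=dim.dimension_label,
            code=code,
            n_patients=int(k),
            prevalence=float(k) / master.n_patients,
        )
        for code, k in counts.items()
        if k >= min_patients
        and not _excluded(feature_id_for(dim.dimension_label, code), exclude)
    ]
    feats.sort(key=lambda f: (-f.prevalence, f.feature_id))
    if n is not None:
        feats = feats[:n]
    if not feats:
        warnings.warn(
            f"dimension '{dim.dimension_label}': no candidate features "
            "survive filtering", stacklevel=2,
        )
    logger.info("dimension '%s': %d candidate feature(s)",
                dim.dimension_label, len(feats))
    return feats


def candidates_frame(features: Sequence[CandidateFeature]) -> pd.DataFrame:
    """Tidy report of candidate features (one row each)."""
    return pd.DataFrame(
        [
            (f.feature_id, f.dimension_label, f.code, f.n_patients, f.prevalence)
            for f in features
        ],
        columns=["feature_id", "dimension_label", "code", "n_patients",
                 "prevalence"],
    )
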