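"""Recurrence assessment: candidate features → binary recurrence covariates.

A code recorded once and a code recorded at every visit carry different
information about underlying health status, so each candidate feature is
expanded into up to three binary covariates per patient:

* ``_once``     — recorded at least once in-window;
* ``_sporadic`` — recorded at least the median number of times;
* ``_frequent`` — recorded at least the 75th-percentile number of times;

with the median and upper quartile computed by the nearest-rank method over
the occurrence counts of patients who have the code at all (the full-cohort
median would usually be zero and collapse all three cutoffs). Covariates
whose cutoffs coincide are deduplicated, keeping the first name in the order
once → sporadic → frequent, so the output never contains two perfectly
collinear columns for the same feature.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .candidates import CandidateFeature
from .cohort_io import CohortMaster, DimensionTable

logger = logging.getLogger(__name__)

SUFFIXES = ("_once", "_sporadic", "_frequent")
QUANTILES = {"_once": None, "_sporadic": 0.5, "_frequent": 0.75}


@dataclass(frozen=True)
class RecurrenceCovariate:
    """One binary covariate: "feature recorded >= cutoff times"."""

    covariate_id: str
    feature_id: str
    cutoff: int


def nearest_rank(sorted_values: np.ndarray, p: float) -> int:
    """Nearest-rank quantile: the ceil(p*m)-th smallest of m values.

    Always returns an observed value, so cutoffs are attainable counts.
    """
    m = len(sorted_values)
    if m == 0:
        raise ValueError("nearest_rank of empty array")
    idx = max(int(math.ceil(p * m)), 1) - 1
    return int(sorted_values[idx])


def count_occurrences(
    dim: DimensionTable, master: CohortMaster, feature_id: str
) -> pd.Series:
    """Per-patient occurrence counts of one feature over the full cohort.

    Every master patient gets a count (0 if absent from the dimension).
    The feature's code is ``feature_id`` minus the dimension prefix.
    """
    prefix = dim.dimension_label + "_"
    if not feature_id.startswith(prefix):
        raise ValueError(
            f"feature '{feature_id}' does not belong to dimension "
            f"'{dim.dimension_label}'"
        )
    code = feature_id[len(prefix):]
    rows = dim.records.loc[dim.records["code"] == code]
    if len(rows) == 0:
        warnings.warn(f"feature '{feature_id}': code absent from dimension; "
                      "all counts zero", stacklevel=2)
    counts = rows.groupby("patient_id").size()
    return counts.reindex(master.patient_ids, fill_value=0).astype(int)


def recurrence_cutoffs(counts: pd.Series | np.ndarray) -> dict[str, int]:
    """Cutoffs {suffix: k} from per-patient counts, deduplicated.

    k_once = 1, k_sporadic = nearest-rank median, k_frequent = nearest-rank
    upper quartile, all over the counts of patients with >= 1 occurrence.
    Suffixes with a cutoff already taken by an earlier suffix are dropped.
    """
    pos = np.sort(np.asarray(counts)[np.asarray(counts) > 0])
    if len(pos) == 0:
        return {}
    raw = {
        "_once": 1,
        "_sporadic": nearest_rank(pos, 0.5),
        "_frequent": nearest_rank(pos, 0.75),
    }
    out: dict[str, int] = {}
    for suffix in SUFFIXES:
        if raw[suffix] not in out.values():
            out[suffix] = raw[suffix]
    return out


def assess_recurrence(
    counts: pd.Series, feature_id: str
) -> tuple[list[RecurrenceCovariate], pd.DataFrame]:
    """Expand one feature's counts into binary recurrence covariates.

    Returns the covariate descriptors and a patients × covariates 0/1
    indicator frame aligned to ``counts``'s index. All counts zero yields an
    empty list with a warning.
    """
    cutoffs = recurrence_cutoffs(counts)
    if not cutoffs:
        warnings.warn(f"feature '{feature_id}': no patient has the code; "
                      "no recurrence covariates generated", stacklevel=2)
        return [], pd.DataFrame(index=counts.index)
    covs = [
        RecurrenceCovariate(feature_id + suffix, feature_id, k)
        for suffix, k in cutoffs.items()
    ]
    arr = np.asarray(counts)[:, None] >= np.array([c.cutoff for c in covs])
    mat = pd.DataFrame(arr.astype(np.int8), index=counts.index,
                       columns=[c.covariate_id for c in covs])
    return covs, mat


def count_matrix(
    dim: DimensionTable, master: CohortMaster,
    features: Sequence[CandidateFeature],
) -> pd.DataFrame:
    """Patients × features occurrence-count matrix for one dimension."""
    codes = [f.code for f in features if f.dimension_label == dim.dimension_label]
    rec = dim.records.loc[dim.records["code"].isin(set(codes))]
    wide = pd.crosstab(rec["patient_id"], rec["code"])
    wide = wide.reindex(index=master.patient_ids, columns=codes, fill_value=0)
    wide.columns = [f"{dim.dimension_label}_{c}" for c in wide.columns]
    return wide.astype(int)


def build_recurrence_matrix(
    dims: Sequence[DimensionTable],
    master: CohortMaster,
    features: Sequence[CandidateFeature],
) -> tuple[pd.DataFrame, list[RecurrenceCovariate]]:
    """Full recurrence expansion across dimensions.

    Returns the wide binary covariate matrix (patients × covariates, aligned
    to the master's patient order) and the covariate descriptors.
    """
    by_label = {d.dimension_label: d for d in dims}
    counts_by_dim = {
        label: count_matrix(dim, master,
                            [f for f in features if f.dimension_label == label])
        for label, dim in by_label.items()
    }
    blocks: list[pd.DataFrame] = []
    covs: list[RecurrenceCovariate] = []
    for f in features:
        if f.dimension_label not in by_label:
            raise ValueError(f"no dimension table labelled '{f.dimension_label}'")
        counts = counts_by_dim[f.dimension_label][f.feature_id]
        c, mat = assess_recurrence(counts, f.feature_id)
        covs.extend(c)
        if len(c):
            blocks.append(mat)
    if not blocks:
        return pd.DataFrame(index=master.patient_ids), covs
    X = pd.concat(blocks, axis=1)
    logger.info("recurrence assessment: %d feature(s) → %d covariate(s)",
                len(features), X.shape[1])
    return X, covs
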