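"""Tabular data model for HDPS cohorts.

Two kinds of table drive the whole pipeline:

* **dimension tables** — long-format records of healthcare codes, one row per
  (patient, code occurrence), one table per aspect of care (diagnoses,
  prescriptions, laboratory tests);
* a **cohort master** — one row per patient carrying the binary exposure,
  the binary outcome, follow-up time, the index (cohort-entry) date and any
  investigator-predefined covariates.

Codes are always handled as text: "250.00" stays "250.00", never 250.0.

Covariate-assessment windows are applied per dimension relative to each
patient's index date using the half-open convention ``[index - L, index)``:
a record dated exactly on the index date is *not* baseline information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import ConfigError, EmptyInputError, SchemaError

logger = logging.getLogger(__name__)

#: column roles every dimension table must provide
DIMENSION_ROLES = ("patient_id", "code")
#: optional role; absent means the table is treated as already window-filtered
OPTIONAL_DIMENSION_ROLES = ("event_date",)

ALL_HISTORY = "all_history"


@dataclass
class DimensionTable:
    """Long-format code records for one data dimension.

    Parameters
    ----------
    dimension_label
        Short label such as ``"dx"``, ``"rx"`` or ``"lab"``; also used as the
        prefix of feature identifiers derived from this dimension.
    records
        DataFrame with columns ``patient_id`` (str), ``code`` (str) and
        optionally ``event_date`` (datetime64). Multiple rows per patient are
        expected; that multiplicity is what recurrence assessment measures.
    meta
        Free-form provenance (e.g. unmapped codes from aggregation).
    """

    dimension_label: str
    records: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.dimension_label:
            raise SchemaError("dimension_label must be a non-empty string")
        missing = [c for c in DIMENSION_ROLES if c not in self.records.columns]
        if missing:
            raise SchemaError(
                f"dimension table '{self.dimension_label}' lacks required "
                f"column(s) {missing}"
            )
        if len(self.records) == 0:
            raise EmptyInputError(
                f"dimension table '{self.dimension_label}' has no records"
            )
        rec = self.records
        for col in DIMENSION_ROLES:
            if rec[col].isna().any() or (rec[col].astype(str) == "").any():
                raise SchemaError(
                    f"column '{col}' of dimension '{self.dimension_label}' "
                    "contains empty values"
                )
        # codes and ids are text, whatever the file said
        for col in DIMENSION_ROLES:
            if rec[col].dtype != object:
                self.records = self.records.assign(**{col: rec[col].astype(str)})
                rec = self.records

    @property
    def has_dates(self) -> bool:
        return "event_date" in self.records.columns

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class WindowSpec:
    """Covariate-assessment window for one dimension.

    ``lookback`` is either the string ``"all_history"`` (every record strictly
    before the index date) or a positive number of days.
    """

    dimension_label: str
    lookback: int | str = ALL_HISTORY

    def __post_init__(self) -> None:
        if self.lookback != ALL_HISTORY:
            if not isinstance(self.lookback, int) or self.lookback <= 0:
                raise ConfigError(
                    f"lookback must be '{ALL_HISTORY}' or a positive integer "
                    f"number of days, got {self.lookback!r}"
                )


@dataclass
class CohortMaster:
    """One row per patient: exposure, outcome, follow-up and covariates.

    ``data`` must contain ``patient_id`` (unique, str), ``exposure`` and
    ``outcome`` (binary 0/1), ``time_to_event`` (>= 0) and, unless every
    dimension table is pre-windowed, ``index_date``. ``predefined`` names the
    investigator-specified covariate columns.
    """

    data: pd.DataFrame
    predefined: tuple[str, ...] = ()
    time_unit: str = "years"

    def __post_init__(self) -> None:
        df = self.data
        required = ("patient_id", "exposure", "outcome", "time_to_event")
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"cohort master lacks required column(s) {missing}")
        if len(df) == 0:
            raise EmptyInputError("cohort master has no patients")
        if df["patient_id"].duplicated().any():
            dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
            raise SchemaError(f"patient_id not unique (e.g. {dup!r})")
        if df["patient_id"].dtype != object:
            self.data = df = df.assign(patient_id=df["patient_id"].astype(str))
        for col in ("exposure", "outcome"):
            vals = set(pd.unique(df[col]))
            if not vals <= {0, 1}:
                raise SchemaError(f"column '{col}' must be binary 0/1, saw {vals}")
            if len(vals) < 2:
                raise SchemaError(
                    f"column '{col}' takes a single value in the cohort; "
                    "prioritisation is undefined"
                )
        if (df["time_to_event"] < 0).any():
            raise SchemaError("time_to_event contains negative values")
        absent = [c for c in self.predefined if c not in df.columns]
        if absent:
            raise SchemaError(f"predefined covariate column(s) {absent} missing")

    @property
    def patient_ids(self) -> pd.Index:
        return pd.Index(self.data["patient_id"])

    @property
    def n_patients(self) -> int:
        return len(self.data)

    def __len__(self) -> int:
        return len(self.data)


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".parquet", ".pq"}:
        return pd.read_parquet(path)
    # everything read as text first; typed roles are converted afterwards
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def load_dimension(
    path: str | Path,
    column_map: Mapping[str, str],
    dimension_label: str,
) -> DimensionTable:
    """Load a long-format dimension table from CSV or Parquet.

    ``column_map`` maps roles (``patient_id``, ``code``, optionally
    ``event_date``) to the file's column names. Row order is preserved and
    codes are kept as text.
    """
    raw = _read_table(path)
    if len(raw) == 0:
        raise EmptyInputError(f"{path}: file contains no records")
    cols = {}
    for role in DIMENSION_ROLES:
        if role not in column_map:
            raise SchemaError(f"column_map lacks required role '{role}'")
        src = column_map[role]
        if src not in raw.columns:
            raise SchemaError(
                f"{path}: column '{src}' (role '{role}') not found; "
                f"available: {list(raw.columns)}"
            )
        cols[role] = raw[src].astype(str)
    if "event_date" in column_map:
        src = column_map["event_date"]
        if src not in raw.columns:
            raise SchemaError(
                f"{path}: column '{src}' (role 'event_date') not found"
            )
        cols["event_date"] = pd.to_datetime(raw[src])
    records = pd.DataFrame(cols)
    logger.info("loaded dimension '%s': %d records from %s",
                dimension_label, len(records), path)
    return DimensionTable(dimension_label=dimension_label, records=records)


def load_master(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    predefined: Sequence[str] = (),
    time_unit: str = "years",
) -> CohortMaster:
    """Load the cohort master sheet from CSV or Parquet.

    ``column_map`` maps the canonical roles to file columns; identity mapping
    is assumed for any role not listed. Predefined covariates keep their names.
    """
    raw = _read_table(path)
    column_map = dict(column_map or {})
    out = {}
    roles = ["patient_id", "exposure", "outcome", "time_to_event", "index_date"]
    for role in roles:
        src = column_map.get(role, role)
        if src not in raw.columns:
            if role == "index_date":
                continue  # optional when dimensions are pre-windowed
            raise SchemaError(f"{path}: column '{src}' (role '{role}') not found")
        out[role] = raw[src]
    out["patient_id"] = out["patient_id"].astype(str)
    for role in ("exposure", "outcome"):
        out[role] = pd.to_numeric(out[role]).astype(int)
    out["time_to_event"] = pd.to_numeric(out["time_to_event"]).astype(float)
    if "index_date" in out:
        out["index_date"] = pd.to_datetime(out["index_date"])
    for col in predefined:
        if col not in raw.columns:
            raise SchemaError(f"{path}: predefined covariate '{col}' not found")
        out[col] = pd.to_numeric(raw[col])
    return CohortMaster(pd.DataFrame(out), predefined=tuple(predefined),
                        time_unit=time_unit)


def apply_window(
    dim: DimensionTable, master: CohortMaster, spec: WindowSpec
) -> DimensionTable:
    """Restrict a dimension table to each patient's assessment window.

    Keeps records with ``index_date - lookback <= event_date < index_date``
    (half-open: index-date records are excluded; ``all_history`` drops only
    the lower bound). Records for patients absent from the master are dropped
    and the count logged — the master defines the cohort.
    """
    if spec.dimension_label != dim.dimension_label:
        raise ConfigError(
            f"window spec is for '{spec.dimension_label}' but table is "
            f"'{dim.dimension_label}'"
        )
    if not dim.has_dates:
        raise SchemaError(
            f"dimension '{dim.dimension_label}' has no event_date column; "
            "windowing requires dates (pre-windowed tables skip this step)"
        )
    if "index_date" not in master.data.columns:
        raise SchemaError("cohort master has no index_date column")

    rec = dim.records
    idx_dates = master.data.set_index("patient_id")["index_date"]
    index_date = rec["patient_id"].map(idx_dates)
    unknown = index_date.isna()
    if unknown.any():
        logger.info(
            "dimension '%s': dropping %d record(s) for %d patient(s) absent "
            "from the master",
            dim.dimension_label, int(unknown.sum()),
            rec.loc[unknown, "patient_id"].nunique(),
        )
    keep = ~unknown & (rec["event_date"] < index_date)
    if spec.lookback != ALL_HISTORY:
        lower = index_date - pd.to_timedelta(spec.lookback, unit="D")
        keep &= rec["event_date"] >= lower
    out = rec.loc[keep]
    logger.info("dimension '%s': window kept %d / %d records",
                dim.dimension_label, len(out), len(rec))
    if len(out) == 0:
        raise EmptyInputError(
            f"dimension '{dim.dimension_label}': no records survive the window"
        )
    return DimensionTable(dim.dimension_label, out, meta=dict(dim.meta))
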