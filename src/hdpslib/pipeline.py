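"""End-to-end HDPS orchestration.

``run_hdps`` chains the seven stages — windowing, code aggregation,
candidate identification, recurrence assessment, Bross prioritisation,
covariate selection + PS/IPTW, weighted Cox estimation — over in-memory
tables and returns every intermediate artifact. ``run_pipeline`` wraps it
for the CLI: reads a YAML config, writes per-stage CSV outputs and a
manifest. ``sweep`` repeats selection + estimation over a grid of top-N
values (the usual sensitivity analysis), reusing the prioritisation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .candidates import (CandidateFeature, GranularityRule, aggregate_codes,
                         candidates_frame, identify_candidates)
from .cohort_io import (ALL_HISTORY, CohortMaster, DimensionTable, WindowSpec,
                        apply_window, load_dimension, load_master)
from .diagnostics import (balance_table, hdps_rank_groups, ps_overlap_summary,
                          summarise_balance, association_map,
                          DEFAULT_RANK_BOUNDARY)
from .errors import ConfigError
from .prioritise import build_association_tables, prioritise, select_top
from .recurrence import RecurrenceCovariate, build_recurrence_matrix
from .weighting import (DEFAULT_TRIM_PERCENTILE, EffectEstimate, PSFit,
                        WeightedCohort, fit_ps, fit_weighted_cox,
                        stabilised_weights)

logger = logging.getLogger(__name__)

#: conventional assessment windows per dimension label
DEFAULT_WINDOWS: dict[str, int | str] = {"dx": ALL_HISTORY, "rx": 90,
                                         "lab": 365}


@dataclass(frozen=True)
class HdpsSettings:
    """Analysis choices for one HDPS run (defaults follow common practice:
    no prevalence filter, zero-cell correction on, top 250 covariates,
    stabilised weights capped at the 99th percentile)."""

    windows: Mapping[str, int | str] | None = None   # None → DEFAULT_WINDOWS
    truncate_dx: int | None = 3                      # ICD-style 3-digit roots
    n_candidates: int | None = None                  # None → no cap
    min_patients: int = 1
    exclude: tuple[str, ...] = ()
    correction: bool = True
    invert_protective: bool = True
    n_select: int = 250
    remove_iv_like: bool = False
    trim_percentile: float = DEFAULT_TRIM_PERCENTILE
    rank_boundary: int = DEFAULT_RANK_BOUNDARY


@dataclass
class HdpsResult:
    """Everything one HDPS run produces."""

    candidates: pd.DataFrame
    covariates: list[RecurrenceCovariate]
    recurrence_matrix: pd.DataFrame
    prioritisation: pd.DataFrame
    selected: list[str]
    ps_predefined: PSFit
    ps_hdps: PSFit
    weights_predefined: WeightedCohort
    weights_hdps: WeightedCohort
    estimates: pd.DataFrame           # crude / predefined / hdps rows
    balance: pd.DataFrame
    balance_summary: pd.DataFrame
    effect_crude: EffectEstimate
    effect_predefined: EffectEstimate
    effect_hdps: EffectEstimate


def _estimate_row(model: str, n_hdps: int, e: EffectEstimate) -> dict:
    return {"model": model, "n_hdps_covariates": n_hdps, "n": e.n,
            "events": e.n_events, "hr": e.hr, "ci_lower": e.ci_lower,
            "ci_upper": e.ci_upper, "log_hr": e.log_hr, "se": e.se}


def prepare_covariates(
    dimensions: Sequence[DimensionTable],
    master: CohortMaster,
    settings: HdpsSettings = HdpsSettings(),
) -> tuple[list[CandidateFeature], pd.DataFrame, list[RecurrenceCovariate],
           pd.DataFrame]:
    """Stages 1–4: window, aggregate, identify candidates, expand recurrence,
    and prioritise. Returns (candidates, recurrence matrix, covariate
    descriptors, prioritisation report)."""
    windows = dict(settings.windows) if settings.windows is not None \
        else DEFAULT_WINDOWS
    prepared: list[DimensionTable] = []
    for dim in dimensions:
        d = dim
        if d.has_dates:
            lookback = windows.get(d.dimension_label, ALL_HISTORY)
            d = apply_window(d, master, WindowSpec(d.dimension_label, lookback))
        if d.dimension_label == "dx" and settings.truncate_dx:
            d = aggregate_codes(d, GranularityRule("dx",
                                                   truncate=settings.truncate_dx))
        prepared.append(d)
    features: list[CandidateFeature] = []
    for d in prepared:
        features.extend(identify_candidates(
            d, master, n=settings.n_candidates,
            min_patients=settings.min_patients, exclude=settings.exclude))
    X, covs = build_recurrence_matrix(prepared, master, features)
    tables = build_association_tables(X, master)
    report = prioritise(tables, correction=settings.correction,
                        invert_protective=settings.invert_protective)
    return features, X, covs, report


def estimate_for_selection(
    master: CohortMaster,
    X: pd.DataFrame,
    selected: list[str],
    settings: HdpsSettings = HdpsSettings(),
) -> tuple[PSFit, WeightedCohort, EffectEstimate]:
    """Stages 6–7 for one covariate selection: PS, weights, weighted Cox."""
    ps = fit_ps(master, X, list(master.predefined) + list(selected))
    wc = stabilised_weights(ps.ps, master.data.set_index("patient_id")
                            ["exposure"].loc[ps.ps.index],
                            trim_percentile=settings.trim_percentile)
    eff = fit_weighted_cox(master, wc.weights)
    return ps, wc, eff


def run_hdps(
    dimensions: Sequence[DimensionTable] | Mapping[str, DimensionTable],
    master: CohortMaster,
    settings: HdpsSettings = HdpsSettings(),
) -> HdpsResult:
    """Full HDPS analysis of one cohort.

    Produces crude, predefined-covariate-weighted and HDPS-weighted hazard
    ratios, the prioritisation report, and balance diagnostics across the
    three weighting schemes.
    """
    if isinstance(dimensions, Mapping):
        dimensions = list(dimensions.values())
    features, X, covs, report = prepare_covariates(dimensions, master,
                                                   settings)
    selected = select_top(report, settings.n_select,
                          remove_iv_like=settings.remove_iv_like)

    ps_pre, wc_pre, eff_pre = estimate_for_selection(master, X, [], settings)
    ps_hdps, wc_hdps, eff_hdps = estimate_for_selection(master, X, selected,
                                                        settings)
    eff_crude = fit_weighted_cox(master, None)

    estimates = pd.DataFrame([
        _estimate_row("crude", 0, eff_crude),
        _estimate_row("predefined", 0, eff_pre),
        _estimate_row("hdps", len(selected), eff_hdps),
    ])

    bal_cols = list(master.predefined) + selected
    bal_X = pd.concat(
        [master.data.set_index("patient_id")[list(master.predefined)],
         X[selected]], axis=1) if bal_cols else pd.DataFrame(index=X.index)
    exposure = master.data.set_index("patient_id")["exposure"]
    sel_report = report.loc[report["covariate_id"].isin(selected)]
    groups = hdps_rank_groups(master.predefined, sel_report,
                              boundary=settings.rank_boundary)
    balance = balance_table(
        bal_X, exposure,
        schemes={"unweighted": None, "predefined": wc_pre.weights,
                 "hdps": wc_hdps.weights},
        groups=groups)
    return HdpsResult(
        candidates=candidates_frame(features),
        covariates=covs, recurrence_matrix=X, prioritisation=report,
        selected=selected, ps_predefined=ps_pre, ps_hdps=ps_hdps,
        weights_predefined=wc_pre, weights_hdps=wc_hdps,
        estimates=estimates, balance=balance,
        balance_summary=summarise_balance(balance),
        effect_crude=eff_crude, effect_predefined=eff_pre,
        effect_hdps=eff_hdps,
    )


def sweep(
    dimensions: Sequence[DimensionTable] | Mapping[str, DimensionTable],
    master: CohortMaster,
    n_select_grid: Sequence[int] = (50, 100, 150, 200, 250, 500),
    settings: HdpsSettings = HdpsSettings(),
) -> pd.DataFrame:
    """Sensitivity sweep over the number of selected HDPS covariates.

    Prioritisation is computed once; selection, PS and the weighted Cox fit
    are redone per grid value. Returns one estimate row per setting.
    """
    if isinstance(dimensions, Mapping):
        dimensions = list(dimensions.values())
    _, X, _, report = prepare_covariates(dimensions, master, settings)
    rows = []
    for n_sel in n_select_grid:
        selected = select_top(report, n_sel,
                              remove_iv_like=settings.remove_iv_like)
        _, _, eff = estimate_for_selection(master, X, selected, settings)
        rows.append(_estimate_row(f"hdps_top_{n_sel}", len(selected), eff))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# config-driven runner (CLI surface)

@dataclass
class PipelineConfig:
    """File-driven description of one analysis run.

    YAML layout::

        master:
          path: master.csv
          column_map: {patient_id: pid}   # optional
          predefined: [age, sex]
          time_unit: years
        dimensions:
          - label: dx
            path: dx.csv
            column_map: {patient_id: pid, code: icd9code, event_date: date}
            window: all_history           # or days (e.g. 90)
            truncate: 3                   # optional
        hdps:
          n_candidates: null
          min_patients: 1
          exclude: []
          correction: true
          n_select: 250
          remove_iv_like: false
          trim_percentile: 99
        seed: 42
        out_dir: results/run1
    """

    master_path: str
    master_column_map: dict
    predefined: tuple[str, ...]
    time_unit: str
    dimensions: list[dict]
    settings: HdpsSettings
    seed: int
    out_dir: str
    raw: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        try:
            m = raw["master"]
            dims = raw["dimensions"]
        except (KeyError, TypeError) as err:
            raise ConfigError(f"config {path} lacks section {err}") from err
        h = raw.get("hdps", {})
        windows = {d["label"]: d.get("window", ALL_HISTORY) for d in dims}
        settings = HdpsSettings(
            windows=windows,
            truncate_dx=next((d.get("truncate") for d in dims
                              if d["label"] == "dx"), None),
            n_candidates=h.get("n_candidates"),
            min_patients=int(h.get("min_patients", 1)),
            exclude=tuple(h.get("exclude", ())),
            correction=bool(h.get("correction", True)),
            n_select=int(h.get("n_select", 250)),
            remove_iv_like=bool(h.get("remove_iv_like", False)),
            trim_percentile=float(h.get("trim_percentile",
                                        DEFAULT_TRIM_PERCENTILE)),
        )
        for d in dims:
            if not Path(d["path"]).exists():
                raise ConfigError(f"dimension file {d['path']} does not exist")
        if not Path(m["path"]).exists():
            raise ConfigError(f"master file {m['path']} does not exist")
        return cls(
            master_path=m["path"],
            master_column_map=m.get("column_map", {}),
            predefined=tuple(m.get("predefined", ())),
            time_unit=m.get("time_unit", "years"),
            dimensions=dims,
            settings=settings,
            seed=int(raw.get("seed", 0)),
            out_dir=raw.get("out_dir", "hdps_output"),
            raw=raw,
        )


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute a config end to end, writing per-stage artifacts.

    Output directory receives candidates.csv, recurrence_matrix.csv,
    prioritisation.csv, selected.txt, weights.csv, estimates.csv,
    balance.csv, balance_summary.csv, association_map.csv and
    manifest.json (config hash, seed, per-stage row counts).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = load_master(config.master_path, config.master_column_map,
                         predefined=config.predefined,
                         time_unit=config.time_unit)
    dims = []
    for d in config.dimensions:
        cm = d.get("column_map",
                   {"patient_id": "patient_id", "code": "code"})
        dims.append(load_dimension(d["path"], cm, d["label"]))
    result = run_hdps(dims, master, config.settings)

    result.candidates.to_csv(out / "candidates.csv", index=False)
    result.recurrence_matrix.to_csv(out / "recurrence_matrix.csv")
    result.prioritisation.to_csv(out / "prioritisation.csv", index=False)
    (out / "selected.txt").write_text("\n".join(result.selected) + "\n")
    pd.DataFrame({
        "patient_id": result.weights_hdps.ps.index,
        "ps_predefined": result.ps_predefined.ps.to_numpy(),
        "ps_hdps": result.ps_hdps.ps.to_numpy(),
        "weight_predefined": result.weights_predefined.weights.to_numpy(),
        "weight_hdps": result.weights_hdps.weights.to_numpy(),
    }).to_csv(out / "weights.csv", index=False)
    result.estimates.to_csv(out / "estimates.csv", index=False)
    result.balance.to_csv(out / "balance.csv", index=False)
    result.balance_summary.to_csv(out / "balance_summary.csv", index=False)
    association_map(result.prioritisation).to_csv(
        out / "association_map.csv", index=False)

    cfg_text = json.dumps(config.raw, sort_keys=True, default=str)
    manifest = {
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "seed": config.seed,
        "stages": {
            "1_dimensions": {d.dimension_label: len(d) for d in dims},
            "2_candidates": len(result.candidates),
            "3_recurrence_covariates": int(result.recurrence_matrix.shape[1]),
            "4_prioritised": len(result.prioritisation),
            "5_selected": len(result.selected),
            "6_ps_patients": int(len(result.ps_hdps.ps)),
            "7_estimates": len(result.estimates),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("pipeline complete: %s", out)
    return out
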