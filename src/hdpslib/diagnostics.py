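"""Balance and overlap diagnostics for HDPS analyses.

* absolute standardised differences (ASD) per covariate under several
  weighting schemes (unweighted / predefined-only / predefined + HDPS),
  with the conventional ASD < 0.10 "well-balanced" threshold;
* propensity-score overlap summaries per arm (deciles, common support,
  shared-bin histograms);
* a covariate-association map (ln rr_ce vs ln rr_cd) with robust-z outlier
  flags, for spotting influential or IV-like covariates.

All diagnostics are plain tidy tables; plotting (optional, matplotlib) is a
thin layer on top and is never needed to compute anything.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

BALANCE_THRESHOLD = 0.10
#: rank after which HDPS covariates are grouped separately in balance plots
DEFAULT_RANK_BOUNDARY = 150


def _weighted_mean_var(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    m = float(np.average(x, weights=w))
    v = float(np.average((x - m) ** 2, weights=w))
    return m, v


def asd(
    x: pd.Series | np.ndarray,
    exposure: pd.Series | np.ndarray,
    weights: pd.Series | np.ndarray | None = None,
) -> float:
    """Absolute standardised difference of one covariate between arms.

    Binary covariates use |p1 - p0| / sqrt((p1(1-p1) + p0(1-p0)) / 2);
    continuous ones the pooled-variance analogue. Identical arms give 0;
    zero pooled variance with unequal means gives +inf (degenerate).
    """
    x = np.asarray(x, dtype=float)
    e = np.asarray(exposure)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    binary = set(np.unique(x)) <= {0.0, 1.0}
    m1, v1 = _weighted_mean_var(x[e == 1], w[e == 1])
    m0, v0 = _weighted_mean_var(x[e == 0], w[e == 0])
    if binary:
        v1, v0 = m1 * (1 - m1), m0 * (1 - m0)
    pooled = (v1 + v0) / 2.0
    if pooled == 0:
        return 0.0 if m1 == m0 else float("inf")
    return abs(m1 - m0) / np.sqrt(pooled)


def balance_table(
    X: pd.DataFrame,
    exposure: pd.Series,
    schemes: Mapping[str, pd.Series | np.ndarray | None],
    groups: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """ASD of every covariate under every weighting scheme.

    ``schemes`` maps a scheme label to per-patient weights (None =
    unweighted). ``groups`` optionally labels covariates (e.g. "predefined",
    "hdps_rank_1_150", "hdps_rank_151_plus"). Returns tidy rows
    (covariate_id, scheme, asd, group).
    """
    e = np.asarray(exposure.loc[X.index] if isinstance(exposure, pd.Series)
                   else exposure)
    rows = []
    for scheme, w in schemes.items():
        wv = None if w is None else (
            np.asarray(w.loc[X.index]) if isinstance(w, pd.Series)
            else np.asarray(w))
        for cov in X.columns:
            rows.append({
                "covariate_id": cov,
                "scheme": scheme,
                "asd": asd(X[cov].to_numpy(), e, wv),
                "group": (groups or {}).get(cov, "covariate"),
            })
    return pd.DataFrame(rows)


def hdps_rank_groups(
    predefined: Sequence[str],
    selected_report: pd.DataFrame,
    boundary: int = DEFAULT_RANK_BOUNDARY,
) -> dict[str, str]:
    """Group labels for balance tables: predefined vs HDPS covariates split
    at a rank boundary (HDPS covariates ranked beyond the top ~150 tend to
    stay less well balanced)."""
    groups = {c: "predefined" for c in predefined}
    for _, row in selected_report.iterrows():
        label = (f"hdps_rank_1_{boundary}" if row["rank"] <= boundary
                 else f"hdps_rank_{boundary + 1}_plus")
        groups[row["covariate_id"]] = label
    return groups


def summarise_balance(
    table: pd.DataFrame, threshold: float = BALANCE_THRESHOLD
) -> pd.DataFrame:
    """Per-scheme count (and fraction) of covariates at or above the
    imbalance threshold."""
    out = []
    for scheme, sub in table.groupby("scheme", sort=False):
        n_bad = int((sub["asd"] >= threshold).sum())
        out.append({"scheme": scheme, "n_covariates": len(sub),
                    "n_imbalanced": n_bad,
                    "frac_imbalanced": n_bad / len(sub) if len(sub) else 0.0})
    return pd.DataFrame(out)


@dataclass
class PSOverlapSummary:
    """Per-arm PS distribution summary for one weighting scheme."""

    scheme: str
    deciles: pd.DataFrame          # rows: arm 0/1; columns: d10..d90 + min/max
    common_support: tuple[float, float]
    histogram: pd.DataFrame        # shared bins: bin_left, bin_right, n1, n0


def ps_overlap_summary(
    ps: pd.Series | np.ndarray,
    exposure: pd.Series | np.ndarray,
    scheme: str = "ps",
    n_bins: int = 20,
) -> PSOverlapSummary:
    """Decile table, common-support range and shared-bin histogram of the PS
    by arm. Common support = [max of per-arm minima, min of per-arm maxima]."""
    p = np.asarray(ps, dtype=float)
    e = np.asarray(exposure)
    qs = np.arange(0.1, 1.0, 0.1)
    rows = {}
    for arm in (0, 1):
        v = p[e == arm]
        rows[arm] = {"min": float(v.min()),
                     **{f"d{int(q * 100)}": float(np.quantile(v, q))
                        for q in qs},
                     "max": float(v.max())}
    deciles = pd.DataFrame(rows).T.rename_axis("arm")
    lo = max(rows[0]["min"], rows[1]["min"])
    hi = min(rows[0]["max"], rows[1]["max"])
    edges = np.linspace(p.min(), p.max(), n_bins + 1)
    n1, _ = np.histogram(p[e == 1], bins=edges)
    n0, _ = np.histogram(p[e == 0], bins=edges)
    hist = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                         "n_exposed": n1, "n_unexposed": n0})
    return PSOverlapSummary(scheme=scheme, deciles=deciles,
                            common_support=(lo, hi), histogram=hist)


def _robust_z(x: np.ndarray) -> np.ndarray:
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return np.zeros_like(x)
    return 0.6745 * (x - med) / mad


def association_map(
    prioritised: pd.DataFrame, z_threshold: float = 3.5
) -> pd.DataFrame:
    """Covariate-association scatter export: (ln rr_ce, ln rr_cd) per
    covariate, the IV-like flag carried over from prioritisation, and an
    outlier flag (|robust z| > threshold on either axis)."""
    log_ce = np.log(prioritised["rr_ce"].to_numpy(dtype=float))
    log_cd = np.log(prioritised["rr_cd"].to_numpy(dtype=float))
    outlier = (np.abs(_robust_z(log_ce)) > z_threshold) | \
              (np.abs(_robust_z(log_cd)) > z_threshold)
    return pd.DataFrame({
        "covariate_id": prioritised["covariate_id"].to_numpy(),
        "log_rr_ce": log_ce,
        "log_rr_cd": log_cd,
        "iv_like": prioritised["iv_like"].to_numpy(dtype=bool),
        "outlier": outlier,
    })


def plot_ps_overlap(summary: PSOverlapSummary, path: str) -> None:
    """Render the shared-bin PS histogram by arm to PNG/SVG (needs
    matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    h = summary.histogram
    width = h["bin_right"] - h["bin_left"]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(h["bin_left"], h["n_exposed"], width=width, align="edge",
           alpha=0.5, label="exposed")
    ax.bar(h["bin_left"], h["n_unexposed"], width=width, align="edge",
           alpha=0.5, label="unexposed")
    ax.set_xlabel("propensity score")
    ax.set_ylabel("patients")
    ax.set_title(f"PS overlap — {summary.scheme}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_balance(table: pd.DataFrame, path: str,
                 threshold: float = BALANCE_THRESHOLD) -> None:
    """Dot plot of per-covariate ASDs by scheme (needs matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, max(3, table["covariate_id"].nunique()
                                           * 0.12)))
    order = (table.groupby("covariate_id")["asd"].max()
             .sort_values().index.tolist())
    ypos = {c: i for i, c in enumerate(order)}
    for scheme, sub in table.groupby("scheme", sort=False):
        ax.plot(sub["asd"], [ypos[c] for c in sub["covariate_id"]],
                "o", ms=3, label=scheme, alpha=0.7)
    ax.axvline(threshold, color="k", ls="--", lw=0.8)
    ax.set_xlabel("absolute standardised difference")
    ax.set_yticks([])
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
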