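"""Claims-like synthetic cohorts with known ground truth.

Real hospital-authority data behind HDPS applications is restricted, so the
generator emulates its structure: three code dimensions (ICD-9-like 3-digit
diagnosis roots with decimal subcodes, BNF-like prescription chapter codes,
laboratory test codes), per-patient recurrence, and confounding driven by a
latent binary "frailty" variable U that no table records directly.

Per patient:

* U ~ Bernoulli(p_u);
* each code's occurrence count is Poisson with a per-code base rate,
  multiplied by ``proxy_rate_multiplier`` when U = 1 and the code belongs to
  the proxy subset — proxy codes are therefore noisy measurements of U, the
  signal HDPS is meant to recover;
* exposure T ~ Bernoulli(expit(alpha0 + alpha1·U + small measured-covariate
  terms));
* survival time ~ Exponential(baseline_hazard · exp(beta_t·T + beta_u·U +
  beta_age_outcome·z_age)), administratively censored at ``censor_time``
  years; the outcome indicator is "event before censoring";
* event dates are back-filled uniformly inside each dimension's assessment
  window (entire history for diagnoses, 90 days for prescriptions, 1 year
  for laboratory tests), strictly before the index date.

Everything is reproducible from the scenario seed. With alpha1 > 0 and
beta_u > 0 the crude hazard ratio is biased upward relative to exp(beta_t);
a PS built on the recurrence covariates of the proxy codes removes most of
that bias — the end-to-end property the pipeline is tested on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_io import CohortMaster, DimensionTable
from .errors import ScenarioError

DAY = pd.Timedelta(days=1)


@dataclass(frozen=True)
class SimulationScenario:
    """All knobs of the generator, with claims-like defaults.

    Defaults describe a moderately confounded antihypertensive-style cohort:
    20 000 patients, a latent confounder of prevalence 0.3 shifting the
    exposure log-odds by 1.0 and the log-hazard by 0.7, proxied by 30 of the
    45 codes, null treatment effect, ~5 events per 100 person-years at
    baseline with 5-year administrative censoring.
    """

    n_patients: int = 20_000
    n_dx_codes: int = 20
    n_rx_codes: int = 15
    n_lab_codes: int = 10
    n_proxy_codes: int = 30
    p_u: float = 0.3
    proxy_rate_multiplier: float = 5.0
    base_rate_range: tuple[float, float] = (0.1, 0.5)  # Poisson mean per code
    alpha0: float = -0.7
    alpha1: float = 1.0
    beta_age_exposure: float = 0.15
    beta_sex_exposure: float = -0.1
    beta_t: float = 0.0            # log true hazard ratio
    beta_u: float = 0.7
    beta_age_outcome: float = 0.3
    baseline_hazard: float = 0.05  # events / person-year
    censor_time: float = 5.0       # years
    dx_history_years: float = 5.0
    rx_window_days: int = 90
    lab_window_days: int = 365
    seed: int = 0

    @property
    def true_hr(self) -> float:
        return float(np.exp(self.beta_t))

    def __post_init__(self) -> None:
        if not 0 < self.p_u < 1:
            raise ScenarioError("p_u must lie in (0, 1)")
        lo, hi = self.base_rate_range
        if lo <= 0 or hi < lo:
            raise ScenarioError("base_rate_range must be positive and ordered")
        if self.baseline_hazard <= 0 or self.censor_time <= 0:
            raise ScenarioError("hazard and censoring time must be positive")
        n_codes = self.n_dx_codes + self.n_rx_codes + self.n_lab_codes
        if not 0 <= self.n_proxy_codes <= n_codes:
            raise ScenarioError(
                f"n_proxy_codes must be in [0, {n_codes}]")


@dataclass
class SimulatedCohort:
    """Generator output: dimension tables, master sheet, and ground truth."""

    dimensions: dict[str, DimensionTable]
    master: CohortMaster
    u: np.ndarray                       # latent confounder per patient
    proxy_codes: dict[str, list[str]]   # per dimension, codes proxying U
    code_rates: dict[str, pd.DataFrame]  # per dimension: code, base_rate, proxy
    scenario: SimulationScenario


def _code_labels(rng: np.random.Generator, scenario: SimulationScenario
                 ) -> dict[str, list[str]]:
    """ICD-9-like dx codes (3-digit root + decimal), BNF-like rx chapter
    codes, LAB### lab codes."""
    roots = rng.choice(np.arange(100, 1000), size=scenario.n_dx_codes,
                       replace=False)
    dx = [f"{r}.{rng.integers(0, 100):02d}" for r in roots]
    rx = []
    while len(rx) < scenario.n_rx_codes:
        c = f"{rng.integers(1, 16)}.{rng.integers(1, 10)}.{rng.integers(1, 10)}"
        if c not in rx:
            rx.append(c)
    lab = [f"LAB{i:03d}" for i in
           rng.choice(np.arange(1000), size=scenario.n_lab_codes,
                      replace=False)]
    return {"dx": dx, "rx": rx, "lab": lab}


def _proxy_split(scenario: SimulationScenario) -> dict[str, int]:
    """Distribute the proxy budget across dimensions proportionally
    (largest-remainder)."""
    sizes = {"dx": scenario.n_dx_codes, "rx": scenario.n_rx_codes,
             "lab": scenario.n_lab_codes}
    total = sum(sizes.values())
    exact = {k: scenario.n_proxy_codes * v / total for k, v in sizes.items()}
    quota = {k: min(int(np.floor(x)), sizes[k]) for k, x in exact.items()}
    rest = scenario.n_proxy_codes - sum(quota.values())
    for k in sorted(sizes, key=lambda k: exact[k] - quota[k], reverse=True):
        if rest == 0:
            break
        if quota[k] < sizes[k]:
            quota[k] += 1
            rest -= 1
    return quota


def _window_days(scenario: SimulationScenario, label: str) -> int:
    return {"dx": int(scenario.dx_history_years * 365),
            "rx": scenario.rx_window_days,
            "lab": scenario.lab_window_days}[label]


def simulate(scenario: SimulationScenario) -> SimulatedCohort:
    """Generate one cohort. Fully deterministic given ``scenario.seed``."""
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_patients
    pids = np.array([f"P{i:07d}" for i in range(n)])

    u = (rng.random(n) < scenario.p_u).astype(int)
    z_age = rng.normal(0.0, 1.0, n)          # standardised age
    age = np.round(62 + 11 * z_age, 1)
    sex = rng.integers(0, 2, n)

    # exposure
    logit = (scenario.alpha0 + scenario.alpha1 * u
             + scenario.beta_age_exposure * z_age
             + scenario.beta_sex_exposure * sex)
    exposure = (rng.random(n) < 1.0 / (1.0 + np.exp(-logit))).astype(int)
    prev = exposure.mean()
    if not 0.05 < prev < 0.95:
        raise ScenarioError(
            f"generated exposure prevalence {prev:.3f} outside (0.05, 0.95); "
            "adjust alpha0/alpha1")

    # outcome: exponential survival with administrative censoring
    rate = scenario.baseline_hazard * np.exp(
        scenario.beta_t * exposure + scenario.beta_u * u
        + scenario.beta_age_outcome * z_age)
    t_event = rng.exponential(1.0 / rate)
    outcome = (t_event < scenario.censor_time).astype(int)
    time_to_event = np.minimum(t_event, scenario.censor_time)
    for arm, label in ((1, "exposed"), (0, "unexposed")):
        if outcome[exposure == arm].sum() == 0:
            raise ScenarioError(f"degenerate scenario: no events in the "
                                f"{label} arm")

    index_date = (pd.Timestamp("2018-01-01")
                  + pd.to_timedelta(rng.integers(0, 365, n), unit="D"))

    codes = _code_labels(rng, scenario)
    quota = _proxy_split(scenario)
    proxy_codes = {k: v[: quota[k]] for k, v in codes.items()}

    lo, hi = scenario.base_rate_range
    dims: dict[str, DimensionTable] = {}
    code_rates: dict[str, pd.DataFrame] = {}
    for label, code_list in codes.items():
        base = rng.uniform(lo, hi, len(code_list))
        is_proxy = np.arange(len(code_list)) < quota[label]
        code_rates[label] = pd.DataFrame(
            {"code": code_list, "base_rate": base, "proxy": is_proxy})
        mult = np.where(is_proxy[None, :] & (u[:, None] == 1),
                        scenario.proxy_rate_multiplier, 1.0)
        counts = rng.poisson(base[None, :] * mult)          # n × codes
        pat_idx, code_idx = np.nonzero(counts)
        reps = counts[pat_idx, code_idx]
        pat_rows = np.repeat(pat_idx, reps)
        code_rows = np.repeat(code_idx, reps)
        window = _window_days(scenario, label)
        offsets = rng.integers(1, window + 1, len(pat_rows))
        records = pd.DataFrame({
            "patient_id": pids[pat_rows],
            "code": np.array(code_list, dtype=object)[code_rows],
            "event_date": index_date[pat_rows]
            - pd.to_timedelta(offsets, unit="D"),
        })
        records = records.sort_values(
            ["patient_id", "event_date"], kind="mergesort"
        ).reset_index(drop=True)
        dims[label] = DimensionTable(label, records)

    master = CohortMaster(
        pd.DataFrame({
            "patient_id": pids,
            "exposure": exposure,
            "outcome": outcome,
            "time_to_event": time_to_event,
            "index_date": index_date,
            "age": age,
            "sex": sex,
        }),
        predefined=("age", "sex"),
        time_unit="years",
    )
    return SimulatedCohort(dimensions=dims, master=master, u=u,
                           proxy_codes=proxy_codes, code_rates=code_rates,
                           scenario=scenario)


FIXTURE_SIZES = {"tiny": 40, "small": 2_000, "medium": 20_000}


def make_fixture(size: str = "small", seed: int = 20240901
                 ) -> SimulatedCohort:
    """Packaged example cohorts for demos and tests (all synthetic).

    * ``tiny`` — 40 patients, 9 codes: every 2x2 table hand-checkable;
    * ``small`` — 2 000 patients, default code mix;
    * ``medium`` — 20 000 patients, the default end-to-end scenario.

    Ground truth (latent confounder, proxy codes, true HR = 1) travels with
    the returned object.
    """
    if size not in FIXTURE_SIZES:
        raise ValueError(f"size must be one of {sorted(FIXTURE_SIZES)}")
    n = FIXTURE_SIZES[size]
    if size == "tiny":
        scenario = SimulationScenario(
            n_patients=n, n_dx_codes=4, n_rx_codes=3, n_lab_codes=2,
            n_proxy_codes=4, baseline_hazard=0.15, seed=seed)
    else:
        scenario = SimulationScenario(n_patients=n, seed=seed)
    return simulate(scenario)


def null_scenario(seed: int = 0, n_patients: int = 20_000) -> SimulationScenario:
    """The reference confounded-null scenario (true HR = 1)."""
    return SimulationScenario(n_patients=n_patients, seed=seed)


def effect_scenario(seed: int = 0, true_hr: float = 0.8,
                    n_patients: int = 20_000) -> SimulationScenario:
    """The reference scenario with a protective treatment effect."""
    return SimulationScenario(n_patients=n_patients, seed=seed,
                              beta_t=float(np.log(true_hr)))
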