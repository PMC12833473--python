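import numpy as np
import pandas as pd
import pytest

from hdpslib import CohortMaster, DimensionTable, make_fixture


@pytest.fixture(scope="session")
def tiny_sim():
    """40-patient synthetic cohort; every 2x2 table hand-checkable."""
    return make_fixture("tiny")


@pytest.fixture(scope="session")
def small_sim():
    """2000-patient synthetic cohort with the default confounded-null
    scenario."""
    return make_fixture("small")


@pytest.fixture
def toy_master():
    """Six hand-written patients with both exposure and outcome values."""
    return CohortMaster(
        pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(6)],
            "exposure": [1, 1, 1, 0, 0, 0],
            "outcome": [1, 0, 0, 1, 1, 0],
            "time_to_event": [1.0, 2.0, 3.0, 1.5, 2.5, 3.5],
            "index_date": pd.to_datetime(["2020-06-01"] * 6),
            "age": [60.0, 65.0, 70.0, 55.0, 62.0, 68.0],
        }),
        predefined=("age",),
    )


@pytest.fixture
def toy_dim():
    """Diagnosis records for the toy cohort, with dates spanning the
    index date."""
    return DimensionTable("dx", pd.DataFrame({
        "patient_id": ["p0", "p0", "p1", "p2", "p3", "p3", "p3", "p9"],
        "code": ["434.91", "434.11", "250.00", "434.91", "250.00", "250.01",
                 "401.1", "434.91"],
        "event_date": pd.to_datetime([
            "2020-05-01", "2020-03-01", "2020-05-31", "2020-06-01",
            "2019-01-01", "2020-03-03", "2020-02-02", "2020-05-01"]),
    }))
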