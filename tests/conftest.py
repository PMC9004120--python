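import numpy as np
import pandas as pd
import pytest

from sevscore import CohortScenario, simulate_cohort


def normal_record(**overrides):
    """An infant admission with every variable in its zero-point band."""
    rec = dict(
        patient_id="X1", age_months=6.0, sex="male",
        sbp=90.0, dbp=55.0, heart_rate=120.0, resp_rate=30.0,
        temperature=37.0, gcs=15, pupils="both_reactive",
        ph=7.38, pco2=40.0, tco2=22.0, pao2=95.0, fio2=0.21,
        base_excess=0.0, glucose=100.0, creatinine=0.4, urea=10.0,
        potassium=4.2, wbc=9.0, platelets=300.0, pt=12.0, ptt=30.0,
        admission_type="emergency", postoperative=False,
        mechanical_ventilation=False, procedure="none",
        risk_diagnosis="none", death_picu=False, death_hospital=False,
        los_picu_days=5.0, los_hospital_days=8.0, hospital="A",
    )
    rec.update(overrides)
    return rec


@pytest.fixture
def record_factory():
    return normal_record


@pytest.fixture(scope="session")
def default_cohort():
    """One complete default-scenario cohort, shared across tests."""
    return simulate_cohort(CohortScenario(seed=20240))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cohort_csv(tmp_path):
    """Write a small schema-conforming cohort CSV and return its path."""

    def _write(rows, name="cohort.csv"):
        path = tmp_path / name
        pd.DataFrame(rows).to_csv(path, index=False)
        return path

    return _write
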