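import logging

import numpy as np
import pandas as pd
import pytest

import kmsacost as k

logging.getLogger("kmsacost").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cfg():
    return k.default_config(n_cases=120, trap_rate=0.03)


@pytest.fixture(scope="session")
def bundle(small_cfg):
    """One full pipeline run shared across tests (seed-fixed)."""
    return k.run_study(small_cfg, seed=11, B=12)


def make_claims(rows):
    """Hand-built claims table from (pid, date, setting, dx, proc, med, nonmed, days)."""
    df = pd.DataFrame(rows, columns=[
        "patient_id", "service_date", "setting", "dx", "proc",
        "medication_cost", "non_medication_cost", "inpatient_days",
    ])
    df["service_date"] = pd.to_datetime(df["service_date"])
    return df


def make_persons(pids, birth="1958-06-01", sex="male", region="Taipei",
                 death=None, end="2019-12-31"):
    return pd.DataFrame({
        "patient_id": list(pids),
        "sex": sex, "birth_date": pd.Timestamp(birth), "region": region,
        "death_date": pd.to_datetime(death) if death else pd.NaT,
        "enroll_end": pd.Timestamp(end),
    })


@pytest.fixture
def hand_claims():
    return make_claims


@pytest.fixture
def hand_persons():
    return make_persons
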