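import warnings

import numpy as np
import pandas as pd
import pytest

from longsig import build_panel, scenario_presets, simulate_cohort

warnings.filterwarnings("ignore", category=FutureWarning)


def make_participants(n, enrol="2020-01-01", months=24, **extra):
    base = pd.Timestamp(enrol)
    df = pd.DataFrame({
        "id": [f"P{i:03d}" for i in range(n)],
        "sex": ["F" if i % 2 == 0 else "M" for i in range(n)],
        "birth_date": base - pd.Timedelta(days=365 * 35),
        "enrolment_date": base,
        "end_date": base + pd.Timedelta(days=30 * months),
    })
    for k, v in extra.items():
        df[k] = v
    return df


def make_episode(pid, drug, start_month, end_month, enrol="2020-01-01", cls=None):
    """Episode covering months [start_month, end_month] inclusive."""
    from longsig.panel import DRUG_CLASS

    base = pd.Timestamp(enrol)
    return {
        "participant_id": pid,
        "drug": drug,
        "drug_class": (cls or DRUG_CLASS[drug].value),
        "start_date": base + pd.Timedelta(days=30 * start_month),
        "end_date": base + pd.Timedelta(days=30 * (end_month + 1)),
    }


def make_event(pid, category, month, enrol="2020-01-01", day=5):
    base = pd.Timestamp(enrol)
    return {
        "participant_id": pid,
        "category": category,
        "subtype": "",
        "event_date": base + pd.Timedelta(days=30 * month + day),
    }


EMPTY_EPISODES = pd.DataFrame(
    columns=["participant_id", "drug", "drug_class", "start_date", "end_date"]
)
EMPTY_EVENTS = pd.DataFrame(columns=["participant_id", "category", "subtype", "event_date"])


@pytest.fixture(scope="session")
def null_sim_small():
    return simulate_cohort(scenario_presets("null", n_patients=300, horizon_months=24, seed=11))


@pytest.fixture(scope="session")
def null_panel_small(null_sim_small):
    r = null_sim_small
    return build_panel(r.participants, r.exposures, r.events, r.labs,
                       monthly_covariates=r.monthly)


@pytest.fixture(scope="session")
def confounded_sim():
    return simulate_cohort(
        scenario_presets("confounded", n_patients=4000, horizon_months=60, seed=21)
    )


@pytest.fixture(scope="session")
def confounded_panel(confounded_sim):
    r = confounded_sim
    return build_panel(r.participants, r.exposures, r.events, r.labs,
                       monthly_covariates=r.monthly)
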