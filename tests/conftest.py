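import numpy as np
import pandas as pd
import pytest

from ampmyield import (SimulationConfig, estimate_b_all, expected_split,
                       make_s_dataset, make_t_dataset,
                       make_validation_dataset, simulate_herds)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_herds=8, cows_per_herd=22, test_days_per_cow=6, seed=101
    )


@pytest.fixture(scope="session")
def truth(small_config):
    """~1,000 simulated cow test days with full AM/PM ground truth."""
    return simulate_herds(small_config)


@pytest.fixture(scope="session")
def s_data(truth):
    return make_s_dataset(truth)


@pytest.fixture(scope="session")
def t_data(truth):
    return make_t_dataset(truth)


@pytest.fixture(scope="session")
def validation(truth):
    return make_validation_dataset(truth)


@pytest.fixture(scope="session")
def b_coeffs(t_data):
    return estimate_b_all(t_data)


@pytest.fixture(scope="session")
def calib(s_data, b_coeffs):
    """Decomposed calibration records (expected AM/PM phenotypes)."""
    return expected_split(s_data, b_coeffs)


def make_t_records(milk, content, session="am", trait="fat"):
    """Hand-built alternate-scheme records for one session and trait."""
    milk = np.asarray(milk, dtype=float)
    content = np.asarray(content, dtype=float)
    df = pd.DataFrame({
        "cow_id": np.arange(len(milk)),
        "herd_id": 0,
        "visit": 0,
        "parity": 1,
        "dim": 100,
        "month": 6,
        "session": session,
        "milk": milk,
    })
    df[f"content_{trait}"] = content
    return df
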