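import numpy as np
import pandas as pd
import pytest

from cvdprevent import (
    ModelContext,
    calibrate,
    generate_epi_schedule,
    generate_population,
    load_risk_parameters,
)


@pytest.fixture(scope="session")
def schedule():
    return generate_epi_schedule()


@pytest.fixture(scope="session")
def population():
    """Mid-sized synthetic survey population shared across tests."""
    return generate_population(2000, seed=1)


@pytest.fixture(scope="session")
def big_population():
    return generate_population(10_000, seed=3)


@pytest.fixture(scope="session")
def risk_params(population, schedule):
    return calibrate(population, schedule, load_risk_parameters())


@pytest.fixture(scope="session")
def risk_params_big(big_population, schedule):
    return calibrate(big_population, schedule, load_risk_parameters())


@pytest.fixture(scope="session")
def ctx():
    return ModelContext()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_profiles(n: int, seed: int) -> pd.DataFrame:
    """Uniformly scattered risk-factor profiles (wider than the generator's)
    for oracle comparisons."""
    r = np.random.default_rng(seed)
    sbp = r.uniform(95, 210, n)
    tc = r.uniform(3.0, 10.0, n)
    return pd.DataFrame(
        {
            "id": np.arange(n),
            "age": r.integers(35, 85, n),
            "sex": np.where(r.random(n) < 0.5, "male", "female"),
            "sbp": sbp,
            "dbp": sbp - r.uniform(20, 70, n),
            "total_chol": tc,
            "hdl_chol": np.minimum(r.uniform(0.6, 2.5, n), tc - 0.5),
            "triglycerides": r.uniform(0.5, 9.0, n),
            "smoker": r.random(n) < 0.3,
            "diabetes": r.random(n) < 0.15,
            "on_bp_drugs": r.random(n) < 0.15,
            "on_lipid_drugs": r.random(n) < 0.1,
            "weight": r.uniform(0.5, 2.0, n),
        }
    )
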