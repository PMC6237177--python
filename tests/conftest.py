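import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from vulnindex import GeneratorConfig, generate_state, load_chhattisgarh

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def district_fixture() -> pd.DataFrame:
    return load_chhattisgarh("district_table")


@pytest.fixture(scope="session")
def tertile_fixture() -> pd.DataFrame:
    return load_chhattisgarh("tertile_table")


@pytest.fixture(scope="session")
def synthetic_state():
    """One deterministic synthetic panel shared across tests."""
    return generate_state(GeneratorConfig(n_districts=27, seed=42))


@pytest.fixture()
def synthetic_table(synthetic_state):
    return synthetic_state[0]
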