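import pandas as pd
import pytest
from hypothesis import HealthCheck, settings
from importlib import resources

from osldose.factors import load_factor_tables
from osldose.synthetic import ScannerTruthModel

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tables():
    return load_factor_tables()


@pytest.fixture(scope="session")
def truth():
    return ScannerTruthModel.from_reference_tables()


@pytest.fixture(scope="session")
def truth_noise_free(truth):
    return truth.noise_free()


@pytest.fixture(scope="session")
def printed_comparison():
    """The packaged reference doses and percent differences (one row per condition)."""
    return pd.read_csv(
        resources.files("osldose.data").joinpath("dose_comparison.csv")
    )
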