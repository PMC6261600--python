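import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from trendsvar import simulate_svar, worked_example

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref_params():
    """Reference parameter set for the three-variable system."""
    return worked_example.params()


@pytest.fixture(scope="session")
def ref_panel(ref_params):
    """Study-sized synthetic panel (T=168 months) at the reference truth."""
    return simulate_svar(ref_params, n_months=168, seed=20240101)


@pytest.fixture(scope="session")
def large_panel(ref_params):
    """Large panel for consistency checks."""
    return simulate_svar(ref_params, n_months=20000, seed=7)
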