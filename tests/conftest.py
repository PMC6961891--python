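import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import shiftdetect as sd
from shiftdetect.ricker import deterministic_trajectory

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def noiseless_series():
    """Factory for noiseless Ricker series with known parameters."""

    def make(r=1.2, k=500.0, n1=100.0, length=12, first_year=1):
        params = sd.RickerParams(r=r, k=k)
        traj = deterministic_trajectory(n1, params, length)
        years = np.arange(first_year, first_year + length)
        return sd.PopulationTimeSeries(years=years, abundances=traj), params

    return make


@pytest.fixture
def one_break_series():
    """A low-noise series with a single large, well-placed K shift."""
    scenario = sd.SimulationScenario(
        breaks=(10,), delta_r=0.25, delta_k=0.75, tau=0.01, seed=2024
    )
    return sd.simulate_series(scenario)
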