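import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from intercoop import (
    BreakingSchedule,
    ModelParams,
    PayoffScheme,
    PopulationConfig,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def bistable_params() -> ModelParams:
    """Coordination-game regime: b/c = 10/3 above the critical ratio 2."""
    return ModelParams(
        payoff=PayoffScheme(b=1.0, c=0.3),
        schedule=BreakingSchedule(k_CC=0.3, k_CD=0.6, k_DD=0.9),
        config=PopulationConfig(
            N1=100, N2=100, L1=300, L2=300, L12=200, p=0.6, W=1e-3, w=0.1
        ),
    )


@pytest.fixture
def defection_params() -> ModelParams:
    """k_CC = k_CD: cooperation can never be stabilized."""
    return ModelParams(
        payoff=PayoffScheme(b=1.0, c=0.3),
        schedule=BreakingSchedule(k_CC=0.6, k_CD=0.6, k_DD=0.9),
        config=PopulationConfig(
            N1=100, N2=100, L1=300, L2=300, L12=200, p=0.6, W=1e-3, w=0.1
        ),
    )


@pytest.fixture
def small_config() -> PopulationConfig:
    return PopulationConfig(N1=20, N2=20, L1=30, L2=30, L12=20, p=0.5, W=0.1, w=0.1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240201)
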