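import warnings

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from panicsim import (
    InterventionConfig,
    NeedsSpec,
    NetworkParams,
    SimulationConfig,
)

# strong-response presets deliberately exceed the nominal Gov range
warnings.filterwarnings(
    "ignore", message="gov_strength > 1", category=UserWarning
)


def make_config(s_mean=0.5, m_mean=0.5, *, n_agents=300, horizon=15,
                seed=1, interventions=None, **kwargs) -> SimulationConfig:
    """Small-population configuration for fast tests."""
    return SimulationConfig(
        network=NetworkParams(n_agents=n_agents),
        needs=NeedsSpec(m0_mean=m_mean, s0_mean=s_mean),
        interventions=interventions or InterventionConfig(),
        horizon=horizon,
        seed=seed,
        **kwargs,
    )


@pytest.fixture
def small_config():
    return make_config()
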