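import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dgei import ScenarioSpec, default_profile, generate_scenario, splice_scenarios

settings.register_profile(
    "dgei",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("dgei")


@pytest.fixture
def profile():
    """The shipped operating point (sleeptime 60, bar 9)."""
    return default_profile()


@pytest.fixture
def clean_gait():
    """20 jitter-free, noise-free standard cycles with ground truth."""
    return generate_scenario(
        ScenarioSpec(n_cycles=20, period_jitter=0.0, amplitude_jitter=0.0, noise_sd=0.0, seed=11)
    )


@pytest.fixture
def walk_stand_walk():
    """Two clean 10-cycle walking bouts around a 300-frame static span."""
    return splice_scenarios(
        [
            ScenarioSpec(n_cycles=10, period_jitter=0.0, amplitude_jitter=0.0, noise_sd=0.0, seed=21),
            ScenarioSpec(kind="static_posture", n_cycles=5, noise_sd=0.0, tremor_rate=1.0, seed=22),
            ScenarioSpec(n_cycles=10, period_jitter=0.0, amplitude_jitter=0.0, noise_sd=0.0, seed=23),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
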