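import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from celladder import BurstLaw, ModelParams

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# Canonical study conditions: transcription rate 0.13 /min, growth rate
# 0.03 /min, threshold 65 molecules, geometric bursts with mean 5.
CANONICAL = dict(k_m=0.13, alpha=0.03, X=65)


@pytest.fixture(scope="session")
def canonical_params() -> ModelParams:
    return ModelParams(
        burst=BurstLaw.geometric(5.0), V_b=1.0, **CANONICAL
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160726)
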