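import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from beebloom.params import ModelParams, baseline_params

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def baseline() -> ModelParams:
    return baseline_params()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_params(rng: np.random.Generator, base: ModelParams, spread: float = 0.5) -> ModelParams:
    """A valid random parameter draw: each entry uniform in base*(1 +- spread)."""
    factors = rng.uniform(1.0 - spread, 1.0 + spread, 15)
    return ModelParams(**{
        name: float(getattr(base, name)) * float(f)
        for name, f in zip(base.as_dict(), factors)
    })
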