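import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from bicnet import Dataset, VariableSpec

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def gaussian_pair(rng):
    """Two correlated continuous columns: A -> B with slope 2."""
    a = rng.normal(size=500)
    b = 2.0 * a + rng.normal(scale=0.5, size=500)
    frame = pd.DataFrame({"A": a, "B": b})
    return Dataset(frame, (VariableSpec("A"), VariableSpec("B")))


@pytest.fixture()
def independent_continuous(rng):
    frame = pd.DataFrame({f"X{i}": rng.normal(size=400) for i in range(4)})
    return Dataset(frame, tuple(VariableSpec(f"X{i}") for i in range(4)))
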