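import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_composition(rng, n):
    """Random point on the n-simplex (normalized exponentials ~ Dirichlet(1))."""
    v = rng.exponential(size=n)
    return v / v.sum()


@pytest.fixture
def simple_table():
    """Tiny fractions table: 5 samples x 3 gates, disturbance after t=2."""
    return pd.DataFrame(
        {
            "time_h": [0.0, 1.0, 2.0, 3.0, 4.0],
            "g1": [0.5, 0.5, 0.5, 0.2, 0.3],
            "g2": [0.3, 0.3, 0.3, 0.3, 0.3],
            "g3": [0.2, 0.2, 0.2, 0.5, 0.4],
        }
    )
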