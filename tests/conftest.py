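import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def toy_expr():
    """5 genes x 4 samples with simple structure."""
    return pd.DataFrame(
        {
            "S1": [1.0, 4.0, 2.0, 0.0, 3.0],
            "S2": [2.0, 3.0, 2.0, 1.0, 3.0],
            "S3": [3.0, 2.0, 2.0, 2.0, 3.0],
            "S4": [4.0, 1.0, 2.0, 3.0, 3.0],
        },
        index=["GA", "GB", "GC", "GD", "GE"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
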