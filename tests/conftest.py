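import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def small_panel():
    """A tiny deterministic long panel: 2 subjects x 4 occasions."""
    import pandas as pd

    return pd.DataFrame(
        {
            "subject": [1, 1, 1, 1, 2, 2, 2, 2],
            "occasion": [1, 2, 3, 4, 1, 2, 3, 4],
            "y": [1.0, 2.0, 1.5, 2.5, 0.5, 1.0, 0.8, 1.2],
            "z": [0.1, -0.2, 0.3, 0.0, -0.1, 0.2, 0.4, -0.3],
            "c": [2.0, 2.0, 2.0, 2.0, -1.0, -1.0, -1.0, -1.0],
        }
    )
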