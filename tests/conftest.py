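import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def one_dyad_table():
    """Minimal epoch table: one dyad, baseline + shock rows."""
    return pd.DataFrame(
        {
            "dyad_id": ["d0", "d0"],
            "epoch": ["baseline", "shock"],
            "freezing_obs": [0.0, 0.5],
            "freezing_dem": [0.02, 0.7],
            "shock_dem": [0.0, 1.0],
            "weeks": [3, 3],
            "strain_obs": [1.0, 1.0],
            "strain_dem": [1.0, 1.0],
            "same_strain": [1, 1],
            "preexposure_obs": [1.0, 1.0],
        }
    )
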