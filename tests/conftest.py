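import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from nblcrash.panel import Covariate, CrashPanel, PanelSchema

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def toy_schema() -> PanelSchema:
    return PanelSchema((
        Covariate("x", "continuous"),
        Covariate("flag", "binary"),
    ))


@pytest.fixture()
def toy_panel(toy_schema) -> CrashPanel:
    """2 segments x 2 periods, handcrafted values."""
    df = pd.DataFrame({
        "segment_id": ["a", "a", "b", "b"],
        "period": [1, 2, 1, 2],
        "y": [0, 2, 1, 0],
        "length_km": [1.5, 1.5, 0.8, 0.8],
        "x": [0.1, -0.4, 0.7, 0.2],
        "flag": [0, 0, 1, 1],
    })
    return CrashPanel(df, toy_schema)


def make_panel(I, T, y=None, x=None, seed=0, length=1.0):
    """Programmatic balanced panel with one continuous covariate ``x``."""
    rng = np.random.default_rng(seed)
    n = I * T
    df = pd.DataFrame({
        "segment_id": np.repeat(np.arange(I), T),
        "period": np.tile(np.arange(T), I),
        "y": y if y is not None else rng.poisson(1.0, n),
        "length_km": length,
        "x": x if x is not None else rng.standard_normal(n),
    })
    return CrashPanel(df, PanelSchema((Covariate("x", "continuous"),)))
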