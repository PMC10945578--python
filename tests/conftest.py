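import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from gdcat import ExpressionPanel
from gdcat.simulate import SimConfig, simulate_panel

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_panel() -> ExpressionPanel:
    """Two tissues, 3 genes, partially overlapping subjects — small enough
    to reason about by hand."""
    a = pd.DataFrame(
        {
            "s1": [1.0, 2.0, 3.0],
            "s2": [2.0, 1.0, 4.0],
            "s3": [3.0, 5.0, 2.0],
            "s4": [4.0, 3.0, 1.0],
        },
        index=["g1", "g2", "g3"],
    )
    b = pd.DataFrame(
        {
            "s3": [2.0, 7.0, 1.0],
            "s4": [4.0, 2.0, 3.0],
            "s5": [1.0, 3.0, 5.0],
            "s6": [3.0, 1.0, 2.0],
        },
        index=["g1", "g2", "g3"],
    )
    return ExpressionPanel({"adipose": a, "liver": b})


@pytest.fixture
def null_panel() -> ExpressionPanel:
    """Independent-noise panel: 3 tissues x 60 genes x 80 subjects."""
    cfg = SimConfig(n_subjects=80, tissues={"a": 60, "b": 60, "c": 60}, seed=99)
    panel, _ = simulate_panel(cfg)
    return panel
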