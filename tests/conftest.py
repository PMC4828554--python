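import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from bsfareg.sfa import PanelDataset
from bsfareg.synthetic import TrueFrontierParams, simulate_frontier_panel


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_panel():
    """20 units x 5 periods with visible inefficiency, plus the true u."""
    params = TrueFrontierParams(beta=(2.0, 0.5, 0.02), sigma_v=0.05, lambda_u=0.1, seed=7)
    return simulate_frontier_panel(20, 5, params), params


@pytest.fixture
def tiny_panel():
    """3 observations, one free coefficient (bare design, no const/trend)."""
    gen = np.random.default_rng(42)
    x = np.array([1.0, 1.3, 0.7])
    y = x * 1.0 + gen.normal(0, 0.3, 3) - np.abs(gen.normal(0, np.sqrt(0.2), 3))
    return PanelDataset(
        units=np.array(["a", "b", "c"], dtype=object),
        periods=np.array([1, 1, 1]),
        y=y,
        X=x[:, None],
    )
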