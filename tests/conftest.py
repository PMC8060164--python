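import numpy as np
import pytest

from ndteflow import EmbeddingSpec, FlowMatrix, TimeSeriesPanel


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def white_panel(rng):
    """Independent white-noise panel: 3 regions, 600 points at TR 0.72 s."""
    return TimeSeriesPanel(data=rng.standard_normal((3, 600)), tr=0.72)


@pytest.fixture
def four_node_flow():
    """Hand-checkable flow matrix with an obvious two-region club {0, 1}."""
    v = np.array(
        [
            [0.0, 0.8, 0.6, 0.6],
            [0.8, 0.0, 0.6, 0.6],
            [0.05, 0.05, 0.0, 0.1],
            [0.05, 0.05, 0.1, 0.0],
        ]
    )
    return FlowMatrix(values=v, region_labels=list("ABCD"), embedding=EmbeddingSpec(T=10))


def ar1_series(rng, n, coef):
    """Stationary unit-variance AR(1) series."""
    x = np.empty(n)
    x[0] = rng.standard_normal()
    eps = rng.standard_normal(n) * np.sqrt(1 - coef**2)
    for t in range(1, n):
        x[t] = coef * x[t - 1] + eps[t]
    return x
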