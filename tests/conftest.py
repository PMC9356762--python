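import numpy as np
import pytest

from excessmort import FarringtonConfig, ScenarioParams, simulate_series


@pytest.fixture
def default_cfg():
    return FarringtonConfig()


@pytest.fixture
def long_null_series():
    """A gapless 7-year null series with trend, seasonality, overdispersion."""
    p = ScenarioParams(
        n_weeks=7 * 52,
        alpha=float(np.log(500.0)),
        beta=3e-4,
        amplitude=0.08,
        k=100.0,
        seed=42,
    )
    series, truth = simulate_series(p)
    return series, truth
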