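import numpy as np
import pandas as pd
import pytest

from simplexscreen import ScreenConfig, simulate_library


@pytest.fixture
def config() -> ScreenConfig:
    return ScreenConfig()


@pytest.fixture
def table1_fractions():
    """The graded-volume amplification series: (volumes µL, fraction amplified)."""
    return [5.0, 10.0, 15.0], [0.264, 0.50, 0.623]


@pytest.fixture
def wildtype_library() -> pd.DataFrame:
    """A degenerate one-mutant library identical to wild type."""
    return pd.DataFrame({
        "mutant_id": ["wt0"], "n_mutations": [0],
        "activity_factor": [1.0], "tolerance_factor": [1.0],
    })


@pytest.fixture
def small_library() -> pd.DataFrame:
    return simulate_library(500, seed=11)


def make_linear_trace(slope_au_per_min: float, intercept: float = 0.2,
                      n_points: int = 13, duration_s: float = 120.0,
                      noise_sd: float = 0.0, seed: int = 0, well: str = "A1"):
    from simplexscreen import AbsorbanceTrace
    t = np.linspace(0.0, duration_s, n_points)
    a = intercept + slope_au_per_min * t / 60.0
    if noise_sd > 0:
        a = a + np.random.default_rng(seed).normal(0, noise_sd, n_points)
    return AbsorbanceTrace(well, t, a)
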