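import numpy as np
import pandas as pd
import pytest

from agbpipe import synthio
from agbpipe.grids import GridGeo, GridStack


@pytest.fixture(scope="session")
def small_scenario():
    """Default 12×12, 10-year biweekly scenario used across module tests."""
    cfg = synthio.SyntheticScenario(seed=7)
    inputs, truth = synthio.generate_scenario(cfg)
    return cfg, inputs, truth


@pytest.fixture()
def monthly_stack():
    """Deterministic 2-year monthly stack on a 3×4 grid."""
    time = pd.DatetimeIndex([pd.Timestamp(year=2000 + y, month=m, day=15)
                             for y in range(2) for m in range(1, 13)])
    rng = np.random.default_rng(42)
    vals = rng.uniform(0.0, 1.0, (24, 3, 4))
    return GridStack(vals, np.zeros(vals.shape, bool), "1", time, GridGeo())


def stack_from(values, units="1", start="2000-01-15"):
    """1-pixel helper stack from a 1-D series."""
    v = np.asarray(values, dtype=float).reshape(-1, 1, 1)
    time = pd.date_range(start, periods=v.shape[0], freq="MS") + pd.Timedelta(days=14)
    return GridStack(v, ~np.isfinite(v), units, time, GridGeo())
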