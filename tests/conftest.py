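import numpy as np
import pandas as pd
import pytest

import fisfus as ff


@pytest.fixture(scope="session")
def fig1_traj():
    return ff.fig1_fixture()


@pytest.fixture(scope="session")
def jitter_traj():
    return ff.jitter_fixture(seed=0)


@pytest.fixture()
def small_fixes():
    """Three fixes of one individual, out of order on purpose."""
    return pd.DataFrame(
        {
            "id": ["a", "a", "a"],
            "time": [12.0, 0.0, 6.0],
            "x": [12.0, 0.0, 6.0],
            "y": [0.0, 0.0, 0.0],
        }
    )


def random_trajectory(rng, n_ind=None, n_steps=None, missing_rate=0.1):
    """Small random-walk trajectory with missing cells, for oracle tests."""
    n = int(n_ind if n_ind is not None else rng.integers(2, 13))
    T = int(n_steps if n_steps is not None else rng.integers(5, 201))
    start = rng.normal(0.0, 60.0, (n, 1, 2))
    xy = start + rng.normal(0.0, 8.0, (n, T, 2)).cumsum(axis=1)
    if missing_rate > 0:
        miss = rng.random((n, T)) < missing_rate
        xy[miss] = np.nan
    return ff.TrajectorySet([f"i{k}" for k in range(n)], 0.0, 6.0, xy)
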