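import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def mean_circ_abs_dev_deg(angles_deg, m_deg):
    """Independent oracle: mean circular absolute deviation, in degrees."""
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    m = np.deg2rad(np.atleast_1d(np.asarray(m_deg, dtype=float)))
    d = np.mod(a[None, :] - m[:, None], 2 * np.pi)
    dev = np.pi - np.abs(np.pi - d)
    return np.rad2deg(dev.mean(axis=1))


def grid_circ_median_dev(angles_deg, grid_step=0.01):
    """Brute-force minimum of the mean circular absolute deviation."""
    grid = np.arange(0.0, 360.0, grid_step)
    dev = mean_circ_abs_dev_deg(angles_deg, grid)
    i = int(np.argmin(dev))
    return float(grid[i]), float(dev[i])
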