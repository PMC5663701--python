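import numpy as np
import pandas as pd
import pytest

from camcheck import get_preset
from camcheck.localize import COLUMNS


@pytest.fixture(scope="session")
def cmos():
    return get_preset("cmos")


@pytest.fixture(scope="session")
def scmos():
    return get_preset("scmos")


def make_table(x, y, frame=None, uncertainty=5.0, intensity=1000.0, sigma=130.0):
    """Build a canonical localization DataFrame from coordinate arrays."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    n = len(x)
    frame = np.zeros(n, dtype=int) if frame is None else np.broadcast_to(frame, (n,))
    df = pd.DataFrame({
        "frame": np.asarray(frame, dtype=int),
        "x_nm": x,
        "y_nm": y,
        "sigma_nm": np.broadcast_to(sigma, (n,)).astype(float),
        "intensity_photon": np.broadcast_to(intensity, (n,)).astype(float),
        "offset_photon": np.full(n, 5.0),
        "bkgstd_photon": np.full(n, 3.0),
        "uncertainty_nm": np.broadcast_to(uncertainty, (n,)).astype(float),
    })
    return df[COLUMNS]


@pytest.fixture
def table_factory():
    return make_table
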