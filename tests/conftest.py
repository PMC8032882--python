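import datetime as dt

import numpy as np
import pandas as pd
import pytest

from grazekit import synth
from grazekit.io_model import Trajectory


def make_trajectory(
    coords,
    start="2017-05-20T10:00:00+00:00",
    interval=60.0,
    collar_id="C1",
):
    """Trajectory from a list of (easting, northing), fixes every `interval` s."""
    coords = np.asarray(coords, dtype=float)
    times = pd.Timestamp(start) + pd.to_timedelta(np.arange(len(coords)) * interval, unit="s")
    return Trajectory(
        collar_id=collar_id,
        times=pd.DatetimeIndex(times),
        easting=coords[:, 0],
        northing=coords[:, 1],
        nominal_interval=interval,
    )


@pytest.fixture(scope="session")
def small_bundle():
    """One replicated scenario over a short period, reused by read-only tests."""
    return synth.scenario_suite(
        seed=20170518,
        n_blocks=1,
        end_date=dt.date(2017, 5, 25),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
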