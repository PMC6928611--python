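import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import grazetrack as gt

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_deployment():
    """A short default-config deployment shared by fast tests."""
    return gt.simulate_deployment(gt.SimConfig(seed=7, n_fixes=600))


@pytest.fixture(scope="session")
def small_gps_features(small_deployment):
    return gt.build_gps_features(small_deployment.trajectory)


@pytest.fixture(scope="session")
def small_accel_features(small_deployment):
    return gt.build_accel_features(small_deployment.accel)


def straight_trajectory(n=40, step=10.0, e0=500_000.0, n0=4_000_000.0):
    """A collinear eastbound track with equal steps, one segment."""
    import pandas as pd

    ts = pd.date_range("2018-09-23 09:00:00", periods=n, freq="50s", tz="UTC")
    return gt.Trajectory(
        animal_id="t",
        timestamps=ts,
        easting=e0 + step * np.arange(n),
        northing=np.full(n, n0),
        zone=51,
        hemisphere="N",
        segment_ids=np.zeros(n, dtype=int),
    )


@pytest.fixture
def straight_traj():
    return straight_trajectory()
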