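import matplotlib
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from trackmotion import AcquisitionConfig, MotionSpec, Trajectory

matplotlib.use("Agg")

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def noiseless_acq():
    return AcquisitionConfig(localization_sigma=0.0, rng_seed=11)


@pytest.fixture
def default_acq():
    return AcquisitionConfig(rng_seed=11)


def make_track(x, y=None, dt=0.6, track_id="t0", **kwargs):
    x = np.asarray(x, dtype=float)
    y = np.zeros_like(x) if y is None else np.asarray(y, dtype=float)
    t = np.arange(len(x)) * dt
    return Trajectory(track_id, t, x, y, **kwargs)
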