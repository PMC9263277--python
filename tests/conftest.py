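import numpy as np
import pytest

from isofv.fv_profiling import Anthropometrics, FVPoint
from isofv.synthetic_data import CohortConfig, sample_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def anthro():
    return Anthropometrics("S01", body_mass=64.0, lever_length=0.4)


@pytest.fixture(scope="session")
def cohort():
    """Default 22-subject synthetic cohort, 3% multiplicative noise."""
    return sample_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def noiseless_cohort():
    return sample_cohort(CohortConfig(seed=7, noise_cv=0.0))


def line_points(f0=28.0, slope=-9.0, velocities=(30, 60, 90, 120, 150, 180, 210, 240, 300),
                lever=0.382):
    """F-v points on an exact line F = f0 + slope * v at the protocol velocities."""
    import math

    pts = []
    for omega in velocities:
        v = omega * math.pi / 180.0 * lever
        pts.append(FVPoint(angular_velocity=float(omega), velocity=v, force=f0 + slope * v))
    return pts


def exact_mean_sd(mean, sd, n, seed=0):
    """A length-n vector with exactly the requested sample mean and SD (ddof=1)."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x
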