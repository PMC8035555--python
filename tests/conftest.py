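import numpy as np
import pytest

from ddmqa import Criteria, DosePlane


@pytest.fixture
def uniform_pair():
    """Identical uniform 40x40 mm measured/calculated planes."""
    calc = DosePlane(np.full((41, 41), 100.0), spacing=(1.0, 1.0),
                     origin=(-20.0, -20.0), label="calculated")
    meas = DosePlane(np.full((6, 6), 100.0), spacing=(7.62, 7.62),
                     origin=(-19.05, -19.05), label="measured")
    return meas, calc


@pytest.fixture
def criteria():
    return Criteria(dose_pct=3.0, distance_mm=2.0, search_radius_mm=1.0)


def random_plane_pair(rng, measured_shape=(10, 10), calc_shape=(21, 21)):
    """A random coarse measured plane over a random fine calculated plane,
    sharing the same physical extent."""
    meas = DosePlane(rng.uniform(5.0, 100.0, size=measured_shape),
                     spacing=(2.0, 2.0), origin=(0.0, 0.0), label="measured")
    calc = DosePlane(rng.uniform(5.0, 100.0, size=calc_shape),
                     spacing=(1.0, 1.0), origin=(-1.0, -1.0), label="calculated")
    return meas, calc
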