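import numpy as np
import pytest

from cbctgamma import GammaCriteria, Mask3D, Volume3D


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def default_criteria():
    return GammaCriteria(3.0, 30.0)


def random_volume_pair(rng, shape=(20, 20, 20), spacing=(1.5, 2.0, 3.0),
                       lo=-150.0, hi=150.0):
    """A random (reference, evaluated, full mask) triple on one grid."""
    ref = Volume3D(rng.uniform(lo, hi, shape).astype(np.float32), spacing)
    ev = Volume3D(rng.uniform(lo, hi, shape).astype(np.float32), spacing)
    mask = Mask3D(np.ones(shape, bool), spacing)
    return ref, ev, mask


@pytest.fixture
def small_phantom_spec():
    """Downscaled neck phantom that keeps unit tests fast."""
    from cbctgamma import PhantomSpec

    return PhantomSpec(
        shape=(48, 48, 24),
        spacing=(3.0, 3.0, 4.0),
        neck_semi_axes=(50.0, 60.0),
        spine_radius=9.0,
        spine_center_y=26.0,
        airway_radius=6.0,
        airway_center_y=-22.0,
        ctv_radius=15.0,
        ctv_center=(14.0, 0.0),
        ctv_z_slices=(8, 15),
    )
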