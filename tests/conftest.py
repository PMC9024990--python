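import numpy as np
import pytest

from lymphopet import EllipseROI, PhantomSpec, VolumeImage, make_phantom, suggest_roi


@pytest.fixture(scope="session")
def default_phantom():
    """Noiseless two-level ellipsoid phantom on the standard PET grid."""
    spec = PhantomSpec(seed=0)
    v, truth = make_phantom(spec)
    return spec, v, truth


@pytest.fixture(scope="session")
def default_roi(default_phantom):
    spec, v, truth = default_phantom
    return suggest_roi(spec, truth)


def two_level_slice(shape=(40, 40), center=(20, 20), radius=8, hot=10.0, cold=1.0):
    """Disk of value ``hot`` on background ``cold``; returns (volume, disk mask)."""
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    disk = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    plane = np.where(disk, hot, cold)
    return VolumeImage(plane[None].astype(float), (1.0, 1.0, 1.0)), disk


@pytest.fixture
def disk_slice():
    return two_level_slice()


@pytest.fixture
def centered_ellipse():
    return EllipseROI(slice_index=0, center=(20.0, 20.0), semi_axes=(14.0, 14.0))
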