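import numpy as np
import pytest

import voxelfd as v


@pytest.fixture(scope="session")
def cube64():
    return v.generate_cube(64)


@pytest.fixture(scope="session")
def plane64():
    return v.generate_plane(64)


@pytest.fixture(scope="session")
def menger4():
    return v.generate_menger(4)


@pytest.fixture(scope="session")
def scales_1_32():
    """Dyadic scales up to 32 voxels at 1 mm spacing."""
    return v.ScaleSet((1, 2, 4, 8, 16, 32), 1.0)


@pytest.fixture(scope="session")
def random_vol16():
    """Seeded 16^3 random binary volume for oracle-equivalence checks."""
    rng = np.random.default_rng(20240917)
    data = (rng.random((16, 16, 16)) < 0.3).astype(np.uint8)
    return v.VoxelVolume(data, (1.0, 1.0, 1.0))


def powerlaw_curve(scale_set, fd, prefactor=1e5, noise_sd=0.0, rng=None):
    """Synthetic box-count curve N(s) = C * s^-fd with log-normal noise."""
    s = scale_set.scales_mm
    log_n = np.log10(prefactor) - fd * np.log10(s)
    if noise_sd > 0:
        log_n = log_n + rng.normal(0, noise_sd, size=len(s))
    return v.BoxCountCurve(scale_set=scale_set, mean_counts=10.0 ** log_n,
                           n_offsets=0)
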