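import numpy as np
import pytest

from hsiwound import (
    SENSOR_GRID,
    PhantomParams,
    generate_phantom,
    load_study_cases,
)


@pytest.fixture(scope="session")
def grid():
    return SENSOR_GRID


@pytest.fixture(scope="session")
def study_records():
    return load_study_cases()


@pytest.fixture(scope="session")
def disk_scene():
    """Default disk phantom: r=20 px, pitch 0.05 cm, sigma=0.01, no halo."""
    return generate_phantom(PhantomParams(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(20230206)


@pytest.fixture()
def random_cube(rng):
    """Small uncalibrated 16-band cube of uint16 counts."""
    from hsiwound import SpectralCube

    values = rng.integers(0, 4096, (5, 7, 16), dtype=np.uint16)
    return SpectralCube(values, SENSOR_GRID, pixel_pitch_cm=0.05)
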