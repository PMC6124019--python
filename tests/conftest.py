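import numpy as np
import pytest

from lungphan4d import MotionModel, PhantomSpec, render_phase_volume


@pytest.fixture(scope="session")
def small_spec():
    """Coarse 2 mm phantom for fast rendering tests (same materials as the
    default, smaller grid)."""
    return PhantomSpec(grid_spacing=(2.0, 2.0, 2.0), grid_extent=(160.0, 120.0, 160.0), seed=7)


@pytest.fixture(scope="session")
def noiseless_spec():
    """Texture-free phantom: lung exactly -625 HU, target exactly -50 HU."""
    return PhantomSpec(
        grid_spacing=(2.0, 2.0, 2.0), grid_extent=(160.0, 120.0, 160.0), texture_sd=0.0, seed=7
    )


@pytest.fixture(scope="session")
def geom_spec():
    """1 mm grid just big enough for sphere-geometry assertions; odd voxel
    counts so voxel centers land on integer mm positions (incl. z = 0)."""
    return PhantomSpec(grid_spacing=(1.0, 1.0, 1.0), grid_extent=(101.0, 101.0, 141.0), seed=7)


@pytest.fixture(scope="session")
def motion15():
    return MotionModel(amplitude_mm=15.0)


@pytest.fixture(scope="session")
def small_phases(small_spec, motion15):
    return [render_phase_volume(small_spec, motion15, p) for p in range(10)]
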