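import numpy as np
import pytest

import limbpet as lp


@pytest.fixture(scope="session")
def table2():
    """The packaged published per-arm results table."""
    return lp.table2_frame()


@pytest.fixture(scope="session")
def table2_records():
    return lp.table2_fixture()


@pytest.fixture(scope="session")
def small_null_phantom():
    """A compact two-cylinder phantom without a hotspot (fast tests)."""
    spec = lp.PhantomSpec(
        dims=(64, 32, 32),
        spacing_mm=(2.0, 2.0, 2.46),
        arm_radius_mm=12.0,
        arm_separation_mm=60.0,
        seed=11,
    )
    return spec, lp.generate_phantom(spec)


@pytest.fixture(scope="session")
def hotspot_phantom():
    """Study-sized phantom with a 150 mL, 8 SD hotspot in the left arm."""
    spec = lp.PhantomSpec(
        arm_radius_mm=40.0,
        arm_separation_mm=120.0,
        hotspot=lp.Hotspot(center_voxel=(33, 64, 31), radius_mm=33.0, amplitude_sd=8.0),
        seed=7,
    )
    return spec, lp.generate_phantom(spec)


@pytest.fixture()
def constant_volume():
    return lp.VoxelVolume(np.full((4, 4, 4), 7.0), (2.0, 2.0, 2.46), units="Bq")
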