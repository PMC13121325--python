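"""Shared fixtures: schedules, bolus inputs, and session-scoped phantoms.

The phantoms are noiseless ideal-resolution instances (no PSF, no motion)
so construction identities hold exactly; noisy variants are built inside
the tests that need them.
"""

import numpy as np
import pytest

from lafovkin.petdata import FrameSchedule, InputFunction, TAC
from lafovkin.phantom import (
    FengParams,
    build_phantom,
    default_fdg_spec,
    default_water_spec,
    feng_input,
)

PHANTOM_SHAPE = (48, 48, 96)  # 144×144×288 mm at 3 mm voxels


@pytest.fixture(scope="session")
def water_schedule() -> FrameSchedule:
    return FrameSchedule.from_durations(
        [5.0] * 12 + [10.0] * 6 + [15.0] * 4 + [30.0] * 4)


@pytest.fixture(scope="session")
def fdg_schedule() -> FrameSchedule:
    return FrameSchedule.from_durations(
        [10.0] * 6 + [30.0] * 4 + [60.0] * 4 + [150.0] * 4 + [300.0] * 9)


@pytest.fixture(scope="session")
def bolus_input(water_schedule) -> InputFunction:
    return feng_input(FengParams(), water_schedule)


@pytest.fixture(scope="session")
def fdg_plasma(fdg_schedule) -> InputFunction:
    from lafovkin.input_function import blood_to_plasma

    blood = feng_input(FengParams(a1=600, a2=22, a3=21, l1=-4.1, l2=-0.12,
                                  l3=-0.01, tau_min=0.5), fdg_schedule)
    return blood_to_plasma(blood, hct=0.40)


@pytest.fixture(scope="session")
def water_phantom():
    """Noiseless ideal radiowater phantom: (image, segmentation, truth)."""
    spec = default_water_spec(seed=1, shape=PHANTOM_SHAPE, voxel_size_mm=3.0,
                              psf_fwhm_mm=0.0)
    return build_phantom(spec)


@pytest.fixture(scope="session")
def fdg_phantom():
    spec = default_fdg_spec(seed=1, shape=(32, 32, 64), voxel_size_mm=3.0,
                            psf_fwhm_mm=0.0)
    return build_phantom(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
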