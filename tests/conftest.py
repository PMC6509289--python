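import numpy as np
import pytest

from srtmkit import (
    PhantomSpec,
    SRTMParameters,
    ThetaGrid,
    TimeActivityCurve,
    build_phantom,
    make_frame_schedule,
    make_reference_tac,
)
from srtmkit.synthetic import DEFAULT_FRAMING, ReferenceCurveSpec


@pytest.fixture(scope="session")
def schedule():
    """The 50-frame, 45-minute acquisition grid (30x10 s, 15x60 s, 5x300 s)."""
    return make_frame_schedule(DEFAULT_FRAMING)


@pytest.fixture(scope="session")
def ref_tac(schedule):
    """Default biexponential reference curve with its exact analytic tail."""
    return make_reference_tac(ReferenceCurveSpec(), schedule)


@pytest.fixture(scope="session")
def grid():
    return ThetaGrid(0.05, 0.4, 100, "log")


@pytest.fixture(scope="session")
def small_phantom():
    """Compact noiseless lesion phantom for image-level tests."""
    spec = PhantomSpec(
        shape=(24, 24, 16),
        voxel_size_mm=0.5,
        lesion_centre_mm=(3.5, 5.5, 3.5),
        lesion_radius_mm=2.0,
        reference_radius_mm=2.5,
    )
    return build_phantom(spec)
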