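import numpy as np
import pytest

from aohu import PhantomParams, make_plaque_law
from aohu.phantom import ScanMeta


@pytest.fixture
def law():
    return make_plaque_law(130.0, 256.0, 1400.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def params():
    return PhantomParams()


@pytest.fixture
def tiny_params():
    """Small-geometry generator for Monte-Carlo tests over many scans.

    One slice, small grid, no plaque, no vertebral trend: the scan-level
    mean hierarchy is what these tests exercise, not per-pixel imaging.
    """
    return PhantomParams(
        slice_shape=(16, 16),
        vessel_radius_px=(4, 5),
        levels=("L3",),
        plaque_prevalence=0.0,
        vertebral_slope_HU_per_level={"non-contrast": 0.0, "arterial": 0.0, "venous": 0.0, "delayed": 0.0},
    )


@pytest.fixture
def arterial_meta():
    return ScanMeta(
        scan_id="TST-00000",
        cohort_tag="TST",
        phase="arterial",
        sex="M",
        age=55.0,
        weight=80.0,
        rng_stream_id=11,
    )
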