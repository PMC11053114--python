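import numpy as np
import pytest

from deltarad.preprocessing import QuantizedROI
from deltarad.synthetic import CohortConfig, generate_cohort
from deltarad.types import ROIMask, VolumeImage

ISO = (1.0, 1.0, 1.0)


def make_quantized(levels, mask=None, spacing=ISO, n_bins=None) -> QuantizedROI:
    """QuantizedROI straight from a level grid (bypassing intensity mapping)."""
    levels = np.asarray(levels, dtype=np.int32)
    if mask is None:
        mask = levels > 0
    levels = levels.copy()
    levels[~mask] = 0
    return QuantizedROI(
        levels=levels,
        mask=np.asarray(mask, bool),
        n_bins=int(n_bins or max(int(levels.max()), 2)),
        spacing=spacing,
    )


def line_roi(values, spacing=ISO) -> QuantizedROI:
    """1 x N x 1 ROI with the given level sequence."""
    arr = np.asarray(values, dtype=np.int32).reshape(1, -1, 1)
    return make_quantized(arr)


@pytest.fixture(scope="session")
def tiny_cohort_config() -> CohortConfig:
    """Small, fast study conditions reused across tests: 16^2 x 10 grids,
    ~400-voxel ellipsoidal ROIs, uniform 8-fraction schedule."""
    return CohortConfig(
        n_patients=6,
        schedules=((40.0, 8),),
        schedule_weights=(1.0,),
        image_shape=(10, 16, 16),
        roi_radius_mm=(8.0, 6.0, 6.0),
        fiducial_count=1,
        fiducial_mask_dilation_mm=2.0,
        drift_effect_size=0.15,
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_cohort_config):
    return generate_cohort(tiny_cohort_config)


def ball_mask(shape, center, radius, spacing=ISO) -> ROIMask:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = sum(((g - c) * s) ** 2 for g, c, s in zip(grids, center, spacing))
    return ROIMask(acc <= radius**2, spacing)
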