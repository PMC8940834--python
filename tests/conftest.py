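import numpy as np
import pytest
from hypothesis import settings

import spectdenoise as sd

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def geom16():
    """Small acquisition geometry matched to a 16^3 grid."""
    return sd.AcquisitionGeometry(n_views=16, detector_rows=16, detector_cols=16, pixel_mm=6.4)


@pytest.fixture(scope="session")
def small_phantom():
    """24^3 LV phantom sized so the shell is fully in-field."""
    lv = sd.LVParams(center_voxel=(11.5, 11.5, 11.5),
                     outer_semi_axes_mm=(30.0, 30.0, 40.0), wall_thickness_mm=12.0)
    return sd.make_phantom(lv, grid_size=24, voxel_mm=6.4, seed=3)


@pytest.fixture(scope="session")
def small_counts(small_phantom):
    """Standard-dose Poisson counts for the small phantom (2e5 total)."""
    geom = sd.AcquisitionGeometry(n_views=16, detector_rows=24, detector_cols=24, pixel_mm=6.4)
    noiseless = sd.project(small_phantom, geom)
    return sd.sample_counts(noiseless, 2e5, seed=11)


@pytest.fixture(scope="session")
def megacount_proj():
    """Projection set with > 1e6 counts for thinning statistics."""
    rng = np.random.default_rng(5)
    geom = sd.AcquisitionGeometry(n_views=8, detector_rows=32, detector_cols=32, pixel_mm=6.4)
    counts = rng.poisson(150.0, geom.shape).astype(np.int64)
    assert counts.sum() > 1_000_000
    return sd.ProjectionSet(geometry=geom, counts=counts)
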