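import numpy as np
import pytest

from mvkvtrack.geometry import ImagingGeometry
from mvkvtrack.simulate import (
    FiducialModel,
    PhantomModel,
    default_phantom,
)
from mvkvtrack.geometry import PatientPoint


@pytest.fixture
def mv_geom():
    return ImagingGeometry.mv(0.0)


@pytest.fixture
def kv_geom():
    return ImagingGeometry.kv(-90.0)


@pytest.fixture
def quiet_phantom():
    """Three-fiducial phantom, no noise/bands, for deterministic checks."""
    ph = default_phantom(noise_sd=0.0)
    return PhantomModel(
        fiducials=ph.fiducials, background=ph.background,
        noise_sd=0.0, band_artifact=None,
    )


@pytest.fixture
def single_fiducial_phantom():
    fid = FiducialModel(center=PatientPoint(0.0, 0.0, 0.0))
    return PhantomModel(fiducials=(fid,), noise_sd=0.0, band_artifact=None)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
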