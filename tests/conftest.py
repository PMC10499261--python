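import numpy as np
import pytest

from arbortrack.synth import ImagingParams


@pytest.fixture(scope="session")
def small_imaging() -> ImagingParams:
    """Small noiseless imaging volume (30×30×40 μm) used for phantom work —
    same voxel pitch as the full acquisition format, fewer voxels."""
    return ImagingParams(
        field_xy_um=30.0,
        pixels_xy=96,
        z_step_um=0.5,
        depth_um=40.0,
        background_level=0.0,
        noise_model=("none", {}),
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
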