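import sys
from dataclasses import replace
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helper

import paintpet as pp


@pytest.fixture
def grid48():
    """48 mm cubic grid at 4 mm step (13^3 points), FOV-centred."""
    return pp.GridGeometry.centered(48.0, 4.0)


@pytest.fixture
def clinical_scanner():
    return pp.preset_scanner("clinical_pmt_4mm")


@pytest.fixture
def delta_scanner(clinical_scanner):
    """Clinical grid with a near-delta PSF (FWHM = 0.1 voxel) and no
    radial FWHM growth: each stop lands in exactly one voxel."""
    return replace(
        clinical_scanner,
        psf_fwhm0=0.4,
        psf_fwhm_axial0=0.4,
        psf_radial_slope=0.0,
    )


@pytest.fixture
def sphere_dtm(grid48):
    return pp.make_shape_dtm(pp.ShapeSpec.sphere(18.0), grid48)


def make_image(values, voxel_size=4.0, centered=True):
    """VoxelImage helper with FOV-centred origin."""
    values = np.asarray(values, dtype=float)
    vox = np.atleast_1d(np.asarray(voxel_size, dtype=float))
    if vox.size == 1:
        vox = np.repeat(vox, 3)
    origin = -(np.asarray(values.shape) - 1) * vox / 2.0 if centered else np.zeros(3)
    return pp.VoxelImage(values=values, voxel_size=vox, origin=origin)
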