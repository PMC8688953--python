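import numpy as np
import pytest

from osteomorph import (TissueLabelVolume, default_gerbil_spec, generate_phantom,
                        segment_volume, delimit)
from osteomorph.segmentation import endocortical_fill


@pytest.fixture(scope="session")
def coarse_phantom():
    """Noise-free default phantom at 36 um voxels (desk-scale)."""
    return generate_phantom(default_gerbil_spec(voxel_um=36.0))


@pytest.fixture(scope="session")
def coarse_segmented(coarse_phantom):
    """Segmentation run from raw attenuation on the coarse phantom."""
    vol, truth = coarse_phantom
    labels, thr = segment_volume(vol)
    return labels, thr


@pytest.fixture(scope="session")
def coarse_delimited(coarse_phantom):
    """Delimitation on the coarse phantom using ground-truth labels."""
    vol, truth = coarse_phantom
    sc, _ = endocortical_fill(truth.labels)
    seg, profile, variation = delimit(vol, truth.labels, sc_mask=sc)
    return seg, profile, variation, sc


def hollow_cylinder_labels(nz=30, n=64, r_outer_vox=26.0, r_inner_vox=14.0,
                           spacing=(9.0, 9.0, 9.0)):
    """Cortical-shell-only cylinder label volume (no cancellous)."""
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    rr = np.hypot(yy - c, xx - c)
    shell = (rr <= r_outer_vox) & (rr > r_inner_vox)
    labels = np.zeros((nz, n, n), dtype=np.uint8)
    labels[:, shell] = 1
    return TissueLabelVolume(labels, spacing)


@pytest.fixture
def hollow_cylinder():
    return hollow_cylinder_labels()
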