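"""Model-independent local thickness via maximal inscribed spheres.

The local thickness at a point x of a binary structure is the diameter of
the largest sphere that both contains x and fits entirely inside the
structure.  The mean of this field over the structure (a volume-weighted
mean, since every voxel contributes) is the model-independent mean
thickness used for Tb.Th; applied to the pore space it yields Tb.Sp.

Implementation: Euclidean distance transform, then spheres are painted in
descending radius order.  Radii are processed in half-voxel bins, so the
thickness field is quantized to one voxel in diameter; each bin's coverage
is obtained as "distance from the bin's centres <= r", which is a second
distance transform rather than an explicit dilation.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["local_thickness"]


def local_thickness(mask: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Local-thickness field (same units as ``spacing``) of a binary mask.

    Returns an array that is 0 outside the mask and holds the
    maximal-inscribed-sphere diameter inside it.
    """
    mask = np.asarray(mask, dtype=bool)
    spacing = tuple(float(s) for s in spacing[-mask.ndim:])
    out = np.zeros(mask.shape, dtype=np.float64)
    if not mask.any():
        return out
    # crop to the mask bounding box: outside it everything is background,
    # so distances (and hence sphere coverage) are unaffected
    bbox = tuple(slice(int(idx.min()), int(idx.max()) + 1)
                 for idx in np.nonzero(mask))
    full_out = out
    mask = mask[bbox]
    out = np.zeros(mask.shape, dtype=np.float64)
    # pad with one background voxel so the crop keeps the exact distances
    # of the original array (everything beyond the bbox was background)
    pad = np.pad(mask, 1)
    inner = (slice(1, -1),) * mask.ndim
    dt = ndimage.distance_transform_edt(pad, sampling=spacing)[inner]
    r_max = float(dt.max())
    step = 0.5 * min(spacing)
    radii = np.arange(step * np.floor(r_max / step), 0.0, -step)
    eps = 1e-9
    for r in radii:
        seeds = dt >= r - eps
        if not seeds.any():
            continue
        d2seed = ndimage.distance_transform_edt(~seeds, sampling=spacing)
        cover = mask & (d2seed <= r + eps) & (out == 0)
        out[cover] = 2.0 * r
    # every voxel's own inscribed sphere is admissible, so the field is
    # never below twice the distance transform; this also catches voxels a
    # binned sphere just missed at its surface
    out = np.where(mask, np.maximum(out, 2.0 * dt), 0.0)
    full_out[bbox] = out
    return full_out
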