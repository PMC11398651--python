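"""VOI voxel-set helpers: boundary shell, interior, bounding-box cropping.

The boundary shell is defined slice-wise (2D, axial): mask minus its
one-voxel 2D erosion. This matches the "Boundary" / "NoBoundary" feature
suffixes and keeps thin 4-slice VOIs from eroding away along Z.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

_STRUCT2D = ndimage.generate_binary_structure(2, 1)


def boundary_shell(mask: np.ndarray) -> np.ndarray:
    """Mask minus its one-voxel in-plane erosion, per slice."""
    mask = np.asarray(mask, dtype=bool)
    er = np.zeros_like(mask)
    for z in range(mask.shape[0]):
        er[z] = ndimage.binary_erosion(mask[z], structure=_STRUCT2D)
    return mask & ~er


def interior(mask: np.ndarray) -> np.ndarray:
    """One-voxel in-plane erosion of the mask (the "NoBoundary" set)."""
    return np.asarray(mask, dtype=bool) & ~boundary_shell(mask)


def voxel_set(mask: np.ndarray, which: str) -> np.ndarray:
    if which == "whole":
        return np.asarray(mask, dtype=bool)
    if which == "boundary":
        return boundary_shell(mask)
    if which == "interior":
        return interior(mask)
    raise ValueError(f"unknown voxel set {which!r}")


def crop_to_mask(vol: np.ndarray, mask: np.ndarray, margin: int = 6,
                 fill: bool = True):
    """Crop volume and mask to the mask bounding box plus an in-plane margin.

    With ``fill=True`` out-of-mask voxels in the crop are replaced by the
    in-mask mean so that every downstream computation (including filter
    responses) depends only on in-mask intensities. ``fill=False`` keeps the
    surrounding tissue, which the sigmoid edge profiles need.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    zs, ys, xs = np.nonzero(mask)
    z0, z1 = zs.min(), zs.max() + 1
    y0 = max(ys.min() - margin, 0)
    y1 = min(ys.max() + 1 + margin, mask.shape[1])
    x0 = max(xs.min() - margin, 0)
    x1 = min(xs.max() + 1 + margin, mask.shape[2])
    m = mask[z0:z1, y0:y1, x0:x1]
    v = np.array(vol[z0:z1, y0:y1, x0:x1], dtype=np.float64)
    if fill:
        v[~m] = v[m].mean()
    return v, m
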