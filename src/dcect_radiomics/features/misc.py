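"""Edge frequency, fractal dimension and spatial-correlation features.

* Edge Frequency: mean magnitude of unit-offset in-plane intensity
  differences between in-mask neighbor pairs, optionally restricted to the
  boundary shell or interior.
* Fractal Dimension: box-counting slope of the in-mask edge map (voxels
  whose local gradient magnitude exceeds the in-mask mean gradient),
  computed per slice and averaged; masks thinner than 4 voxels per in-plane
  axis return the degenerate value 0.
* Spatial Correlation: 2 * (1 + r1), where r1 is the mean lag-1 in-plane
  Pearson autocorrelation of in-mask neighbor pairs. Smooth images saturate
  at 4; a checkerboard approaches 0; a constant VOI is defined as perfectly
  smooth (4).
"""

from __future__ import annotations

import warnings

import numpy as np

from .masks import voxel_set


def _neighbor_pairs(vol, mask, sample_mask, axis):
    """In-plane neighbor value pairs (v[i], v[i+1]) with both voxels in-mask
    and the first voxel in the sampling set."""
    sl_a = [slice(None)] * 3
    sl_b = [slice(None)] * 3
    sl_a[axis] = slice(0, -1)
    sl_b[axis] = slice(1, None)
    sl_a, sl_b = tuple(sl_a), tuple(sl_b)
    ok = mask[sl_a] & mask[sl_b] & sample_mask[sl_a]
    return vol[sl_a][ok], vol[sl_b][ok]


def edge_frequency(vol: np.ndarray, mask: np.ndarray, which: str = "whole") -> float:
    vol = np.asarray(vol, float)
    mask = np.asarray(mask, bool)
    sample = voxel_set(mask, which)
    diffs = []
    for axis in (1, 2):
        a, b = _neighbor_pairs(vol, mask, sample, axis)
        diffs.append(np.abs(a - b))
    diffs = np.concatenate(diffs) if diffs else np.zeros(0)
    return float(diffs.mean()) if diffs.size else 0.0


def box_counting_dimension(binary2d: np.ndarray) -> float:
    """Box-counting dimension of a 2D point set (log N vs log 1/s slope)."""
    binary2d = np.asarray(binary2d, bool)
    if not binary2d.any():
        return 0.0
    n = max(binary2d.shape)
    sizes = [s for s in (1, 2, 4, 8, 16, 32) if s <= n // 2]
    if len(sizes) < 2:
        return 0.0
    counts = []
    for s in sizes:
        h = int(np.ceil(binary2d.shape[0] / s))
        w = int(np.ceil(binary2d.shape[1] / s))
        pad = np.zeros((h * s, w * s), bool)
        pad[:binary2d.shape[0], :binary2d.shape[1]] = binary2d
        boxes = pad.reshape(h, s, w, s).any(axis=(1, 3))
        counts.append(boxes.sum())
    slope, _ = np.polyfit(np.log(1.0 / np.asarray(sizes, float)),
                          np.log(np.asarray(counts, float)), 1)
    return float(slope)


def _edge_map(vol2d, mask2d):
    gy, gx = np.gradient(vol2d)
    gmag = np.hypot(gy, gx)
    gmag[~mask2d] = 0.0
    if not mask2d.any():
        return np.zeros_like(mask2d)
    thr = gmag[mask2d].mean()
    return mask2d & (gmag > thr)


def fractal_dimension(vol: np.ndarray, mask: np.ndarray) -> float:
    vol = np.asarray(vol, float)
    mask = np.asarray(mask, bool)
    ys, xs = np.nonzero(mask.any(axis=0))
    if ys.size == 0 or (ys.max() - ys.min() + 1) < 4 or (xs.max() - xs.min() + 1) < 4:
        warnings.warn("mask too small for box counting; Fractal Dimension set to 0")
        return 0.0
    dims = []
    for z in range(vol.shape[0]):
        if not mask[z].any():
            continue
        em = _edge_map(vol[z], mask[z])
        if em.any():
            d = box_counting_dimension(em)
            if d > 0:
                dims.append(d)
    return float(np.mean(dims)) if dims else 0.0


def spatial_correlation(vol: np.ndarray, mask: np.ndarray) -> float:
    vol = np.asarray(vol, float)
    mask = np.asarray(mask, bool)
    rs = []
    for axis in (1, 2):
        a, b = _neighbor_pairs(vol, mask, mask, axis)
        if a.size < 3:
            continue
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            rs.append(1.0)  # constant VOI: perfectly smooth by convention
        else:
            rs.append(float(np.corrcoef(a, b)[0, 1]))
    r1 = float(np.mean(rs)) if rs else 1.0
    return 2.0 * (1.0 + r1)


def misc_texture_features(vol: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    return {
        "Edge Frequency": edge_frequency(vol, mask, "whole"),
        "Edge Frequency Boundary": edge_frequency(vol, mask, "boundary"),
        "Edge Frequency NoBoundary": edge_frequency(vol, mask, "interior"),
        "Fractal Dimension": fractal_dimension(vol, mask),
        "Spatial Correlation": spatial_correlation(vol, mask),
    }
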