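"""Gray-tone difference matrix features (Amadasun-King).

The neighborhood is the 3x3 in-plane ring around each voxel; a voxel
contributes if at least one in-mask neighbor exists. Per gray level i the
matrix stores the occupancy n_i and the summed absolute difference
s_i = sum |i - mean(in-mask neighbors)|. Counts are accumulated over all
slices before the features are formed. Degenerate limits: a constant VOI has
all s_i = 0, giving Strength = Complexity = Contrast = Busyness = 0
(Coarseness, whose formula diverges, is reported as 0 as the documented
degenerate value).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .quantize import QuantizedVolume

_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=float)


def gtdm_matrix(q: QuantizedVolume, mask: np.ndarray | None = None):
    """Return (s, n) arrays indexed by gray level 1..n_levels (position 0 unused)."""
    mask = q.mask if mask is None else np.asarray(mask, dtype=bool)
    nl = q.n_levels
    s = np.zeros(nl + 1)
    n = np.zeros(nl + 1)
    for z in range(q.labels.shape[0]):
        m = mask[z]
        if not m.any():
            continue
        lab = q.labels[z].astype(float)
        cnt = ndimage.convolve(m.astype(float), _KERNEL, mode="constant", cval=0.0)
        tot = ndimage.convolve(np.where(m, lab, 0.0), _KERNEL, mode="constant", cval=0.0)
        valid = m & (cnt > 0)
        if not valid.any():
            continue
        nbr_mean = tot[valid] / cnt[valid]
        levels = q.labels[z][valid]
        diffs = np.abs(levels - nbr_mean)
        np.add.at(s, levels, diffs)
        np.add.at(n, levels, 1.0)
    if n.sum() == 0:
        raise ValueError("no voxel has an in-mask neighborhood")
    return s, n


def gtdm_features(q: QuantizedVolume, mask: np.ndarray | None = None) -> dict[str, float]:
    s, n = gtdm_matrix(q, mask)
    N = n.sum()
    p = n / N
    present = np.nonzero(n)[0]
    i = np.arange(len(n), dtype=float)
    ngp = present.size

    ps_sum = float((p * s).sum())
    s_sum = float(s.sum())

    coarseness = 1.0 / ps_sum if ps_sum > 0 else 0.0

    contrast = 0.0
    if ngp > 1:
        ii, jj = np.meshgrid(present, present, indexing="ij")
        pij = p[ii] * p[jj]
        contrast = float((pij * (ii - jj) ** 2).sum() / (ngp * (ngp - 1))
                         * (s_sum / N))

    busyness = 0.0
    if ngp > 1 and ps_sum > 0:
        ii, jj = np.meshgrid(present, present, indexing="ij")
        denom = float(np.abs(ii * p[ii] - jj * p[jj]).sum())
        busyness = ps_sum / denom if denom > 0 else 0.0

    complexity = 0.0
    if ngp > 1:
        ii, jj = np.meshgrid(present, present, indexing="ij")
        pi, pj = p[ii], p[jj]
        complexity = float((np.abs(ii - jj) * (pi * s[ii] + pj * s[jj])
                            / (pi + pj)).sum() / N)

    strength = 0.0
    if s_sum > 0 and ngp > 1:
        ii, jj = np.meshgrid(present, present, indexing="ij")
        strength = float(((p[ii] + p[jj]) * (ii - jj) ** 2).sum() / s_sum)

    return {
        "GTDM Strength": strength, "GTDM Complexity": complexity,
        "GTDM Coarseness": coarseness, "GTDM Busyness": busyness,
        "GTDM Contrast": contrast,
    }
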