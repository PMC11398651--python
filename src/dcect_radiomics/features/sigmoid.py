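"""Sigmoid edge-profile features of the lesion boundary.

For a deterministic, evenly spaced subsample of boundary voxels, the HU
profile along the 2D outward surface normal (from the gradient of the mask's
distance transform) is sampled at 11 unit steps centered on the boundary
voxel, and the logistic edge model

    f(t) = offset + amplitude / (1 + exp((t - center) / width))

is fitted by least squares. With t increasing outward, ``amplitude`` is the
inside-minus-outside edge height (positive for a lesion brighter than its
surroundings) and ``offset`` the outside plateau. The fit profiles over a
fixed (center, width) grid on which the model is linear in (offset,
amplitude); each profile takes the grid point with the smallest residual.
Profiles with a runaway solution are dropped; the features are the mean and
SD of amplitude, offset and width over the surviving profiles.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .masks import boundary_shell

PROFILE_LEN = 11
MAX_PROFILES = 48
_CENTERS = (-2.0, -1.0, 0.0, 1.0, 2.0)
_WIDTHS = (0.4, 0.7, 1.0, 1.5, 2.5)


def _profiles(vol: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """(P, PROFILE_LEN) HU profiles along outward normals of boundary voxels."""
    t = np.arange(PROFILE_LEN, dtype=float) - (PROFILE_LEN - 1) / 2.0
    shell = boundary_shell(mask)
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    sdist = ndimage.gaussian_filter(outside - inside, sigma=1.0)  # increases outward
    gy, gx = np.gradient(sdist, axis=(1, 2))
    zs, ys, xs = np.nonzero(shell)
    if zs.size == 0:
        raise ValueError("boundary shell is empty")
    step = max(1, zs.size // MAX_PROFILES)
    rows = []
    for i in range(0, zs.size, step):
        z, y, x = zs[i], ys[i], xs[i]
        ny, nx = gy[z, y, x], gx[z, y, x]
        norm = np.hypot(ny, nx)
        if norm == 0:
            continue
        ny, nx = ny / norm, nx / norm
        coords = np.vstack([np.clip(y + t * ny, 0, vol.shape[1] - 1),
                            np.clip(x + t * nx, 0, vol.shape[2] - 1)])
        rows.append(ndimage.map_coordinates(vol[z], coords, order=1, mode="nearest"))
    if not rows:
        raise ValueError("no boundary profiles available")
    return np.asarray(rows)


def _fit_logistic(profiles: np.ndarray):
    """Vectorized least-squares fit over the (center, width) grid.

    Returns (offset, amplitude, width) arrays, one entry per profile.
    """
    t = np.arange(PROFILE_LEN, dtype=float) - (PROFILE_LEN - 1) / 2.0
    n_prof = profiles.shape[0]
    best_rss = np.full(n_prof, np.inf)
    best = np.zeros((3, n_prof))
    y_sum = profiles.sum(axis=1)
    for w in _WIDTHS:
        for c in _CENTERS:
            s = 1.0 / (1.0 + np.exp((t - c) / w))
            # linear LSQ in (offset, amplitude) with shared design [1, s]
            n, s1, s2 = PROFILE_LEN, s.sum(), (s * s).sum()
            det = n * s2 - s1 * s1
            ys = profiles @ s
            amp = (n * ys - s1 * y_sum) / det
            off = (y_sum - amp * s1) / n
            resid = profiles - off[:, None] - amp[:, None] * s[None, :]
            rss = (resid ** 2).sum(axis=1)
            upd = rss < best_rss
            best_rss[upd] = rss[upd]
            best[0, upd] = off[upd]
            best[1, upd] = amp[upd]
            best[2, upd] = w
    return best[0], best[1], best[2]


def sigmoid_boundary_features(vol: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    profiles = _profiles(np.asarray(vol, float), np.asarray(mask, bool))
    offs, amps, widths = _fit_logistic(profiles)
    rng_v = profiles.max(axis=1) - profiles.min(axis=1)
    ok = np.abs(amps) <= 10.0 * np.maximum(rng_v, 1.0)  # drop runaway fits
    if not ok.any():
        raise ValueError("all sigmoid fits failed")
    amps, offs, widths = amps[ok], offs[ok], widths[ok]
    return {
        "Sigmoid Amplitude Mean": float(amps.mean()),
        "Sigmoid Amplitude Std": float(amps.std()),
        "Sigmoid Offset Mean": float(offs.mean()),
        "Sigmoid Offset Std": float(offs.std()),
        "Sigmoid Width Mean": float(widths.mean()),
        "Sigmoid Width Std": float(widths.std()),
    }
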