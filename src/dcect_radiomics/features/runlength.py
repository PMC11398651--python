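"""Gray-level run-length features (Galloway / Chu emphasis statistics).

Runs are maximal streaks of equal gray level along a direction, restricted to
in-mask voxels (a gap in the mask terminates a run). Matrices are built
slice-wise for the four in-plane directions; features are computed per
direction, averaged over directions, then averaged over slices.
"""

from __future__ import annotations

import numpy as np

from .quantize import QuantizedVolume

DIRECTIONS_2D = ((0, 1), (1, 0), (1, 1), (1, -1))


def _lines(shape, direction):
    """Index arrays of all maximal lattice lines of a 2D grid along a direction."""
    h, w = shape
    dy, dx = direction
    starts = []
    if (dy, dx) == (0, 1):
        starts = [(y, 0) for y in range(h)]
    elif (dy, dx) == (1, 0):
        starts = [(0, x) for x in range(w)]
    elif (dy, dx) == (1, 1):
        starts = [(0, x) for x in range(w)] + [(y, 0) for y in range(1, h)]
    elif (dy, dx) == (1, -1):
        starts = [(0, x) for x in range(w)] + [(y, w - 1) for y in range(1, h)]
    else:
        raise ValueError(f"unsupported direction {direction}")
    for y0, x0 in starts:
        ys, xs = [], []
        y, x = y0, x0
        while 0 <= y < h and 0 <= x < w:
            ys.append(y)
            xs.append(x)
            y += dy
            x += dx
        yield np.array(ys), np.array(xs)


def run_length_matrix(labels2d: np.ndarray, mask2d: np.ndarray, direction,
                      n_levels: int) -> np.ndarray:
    """R[g-1, l-1] = number of runs of gray level g and length l."""
    max_len = max(labels2d.shape)
    mat = np.zeros((n_levels, max_len))
    for ys, xs in _lines(labels2d.shape, direction):
        vals = labels2d[ys, xs]
        inm = mask2d[ys, xs]
        run_val, run_len = None, 0
        for v, m in zip(vals, inm):
            if m and v == run_val:
                run_len += 1
            else:
                if run_len:
                    mat[run_val - 1, run_len - 1] += 1
                run_val, run_len = (int(v), 1) if m else (None, 0)
        if run_len:
            mat[run_val - 1, run_len - 1] += 1
    return mat


def run_length_features_single(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    """Emphasis statistics of one run-length matrix."""
    nr = mat.sum()
    if nr == 0:
        raise ValueError("no runs in matrix")
    g = np.arange(1, mat.shape[0] + 1, dtype=float)[:, None]
    l = np.arange(1, mat.shape[1] + 1, dtype=float)[None, :]
    return {
        "RSR Emphasis": float((mat / l**2).sum() / nr),
        "RLR Emphasis": float((mat * l**2).sum() / nr),
        "RGL Uniformity": float((mat.sum(axis=1) ** 2).sum() / nr),
        "RPL Uniformity": float((mat.sum(axis=0) ** 2).sum() / nr),
        "RHGLR Emphasis": float((mat * g**2).sum() / nr),
        "RLGLR Emphasis": float((mat / g**2).sum() / nr),
        "RSRLGL Emphasis": float((mat / (g**2 * l**2)).sum() / nr),
        "RSRHGL Emphasis": float((mat * g**2 / l**2).sum() / nr),
        "RLRHGL Emphasis": float((mat * g**2 * l**2).sum() / nr),
        "RLRLGL Emphasis": float((mat * l**2 / g**2).sum() / nr),
        "Run Percentage": float(nr / n_voxels),
    }


def run_length_features(q: QuantizedVolume, mask: np.ndarray | None = None) -> dict[str, float]:
    mask = q.mask if mask is None else np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    per_slice = []
    for z in range(q.labels.shape[0]):
        if not mask[z].any():
            continue
        n_vox = int(mask[z].sum())
        per_dir = [run_length_features_single(
            run_length_matrix(q.labels[z], mask[z], d, q.n_levels), n_vox)
            for d in DIRECTIONS_2D]
        per_slice.append({k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]})
    return {k: float(np.mean([f[k] for f in per_slice])) for k in per_slice[0]}
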