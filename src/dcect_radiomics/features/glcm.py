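"""Haralick gray-level co-occurrence features.

Computed slice-wise (axial 2D) at distance 1 over the four in-plane
directions (0, 45, 90, 135 degrees). Each direction yields a symmetric,
normalized co-occurrence matrix restricted to in-mask voxel pairs; features
are computed per direction, averaged over directions with at least one valid
pair, then averaged over slices. Logarithms are base 2; degenerate
single-gray-level matrices take the documented limits (Correlation 1, MCC 1,
IMC2 0).
"""

from __future__ import annotations

import numpy as np

from .quantize import QuantizedVolume

DIRECTIONS_2D = ((0, 1), (1, 1), (1, 0), (1, -1))

_EPS = np.finfo(float).tiny


def glcm_matrix(labels2d: np.ndarray, mask2d: np.ndarray, direction,
                n_levels: int) -> np.ndarray | None:
    """Symmetric normalized co-occurrence matrix for one slice/direction,
    or None when the direction has no valid in-mask pair."""
    dy, dx = direction
    h, w = labels2d.shape
    ys, xs = np.nonzero(mask2d)
    y2, x2 = ys + dy, xs + dx
    ok = (y2 >= 0) & (y2 < h) & (x2 >= 0) & (x2 < w)
    ys, xs, y2, x2 = ys[ok], xs[ok], y2[ok], x2[ok]
    ok = mask2d[y2, x2]
    if not ok.any():
        return None
    a = labels2d[ys[ok], xs[ok]] - 1
    b = labels2d[y2[ok], x2[ok]] - 1
    mat = np.zeros((n_levels, n_levels))
    np.add.at(mat, (a, b), 1.0)
    mat = mat + mat.T
    return mat / mat.sum()


def _features_from_matrix(p: np.ndarray) -> dict[str, float]:
    n = p.shape[0]
    i = np.arange(1, n + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu_x = float((i * px).sum())
    sig_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))

    # sum and difference distributions
    ks = np.arange(2, 2 * n + 1, dtype=float)
    p_sum = np.zeros(ks.size)
    kd = np.arange(0, n, dtype=float)
    p_diff = np.zeros(kd.size)
    for a in range(n):
        for b in range(n):
            p_sum[a + b] += p[a, b]
            p_diff[abs(a - b)] += p[a, b]

    def ent(q):
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum()) if q.size else 0.0

    contrast = float(((ii - jj) ** 2 * p).sum())
    autocorr = float((ii * jj * p).sum())
    if sig_x > 0:
        correlation = (autocorr - mu_x * mu_x) / (sig_x * sig_x)
    else:
        correlation = 1.0
    asm = float((p ** 2).sum())
    entropy = ent(p.ravel())
    sum_entropy = ent(p_sum)
    diff_entropy = ent(p_diff)
    diff_avg = float((kd * p_diff).sum())
    diff_var = float(((kd - diff_avg) ** 2 * p_diff).sum())
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())
    homogeneity = float((p / (1.0 + np.abs(ii - jj))).sum())
    dev = ii + jj - 2.0 * mu_x
    cluster_tendency = float((dev ** 2 * p).sum())
    cluster_shade = float((dev ** 3 * p).sum())
    cluster_prominence = float((dev ** 4 * p).sum())
    sum_avg = float((ks * p_sum).sum())
    sum_var = float(((ks - sum_avg) ** 2 * p_sum).sum())
    dissimilarity = float((np.abs(ii - jj) * p).sum())
    max_prob = float(p.max())

    hx = ent(px)
    pxpy = np.outer(px, px)
    hxy1 = float(-(p[pxpy > 0] * np.log2(pxpy[pxpy > 0])).sum())
    hxy2 = ent(pxpy.ravel())
    imc1 = (entropy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    if n > 1 and (px > 0).sum() > 1:
        # Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k)); MCC = sqrt(second eigenvalue)
        with np.errstate(divide="ignore", invalid="ignore"):
            q = (p / np.where(px[:, None] > 0, px[:, None], 1.0)) @ (
                p / np.where(px[None, :] > 0, px[None, :], 1.0)).T
        ev = np.sort(np.real(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(max(0.0, ev[-2]))) if ev.size > 1 else 1.0
    else:
        mcc = 1.0

    return {
        "GLCM Contrast": contrast, "GLCM Correlation": float(correlation),
        "GLCM Sum Squares": float(sig_x ** 2), "GLCM ASM": asm,
        "GLCM Entropy": entropy, "GLCM Sum Entropy": sum_entropy,
        "GLCM Diff Entropy": diff_entropy, "GLCM Diff Variance": diff_var,
        "GLCM IDM": idm, "GLCM Homogeneity": homogeneity,
        "GLCM Cluster Tendency": cluster_tendency, "GLCM IMC1": float(imc1),
        "GLCM IMC2": imc2, "GLCM MCC": mcc, "GLCM Max Prob": max_prob,
        "GLCM Sum Average": sum_avg, "GLCM Sum Variance": sum_var,
        "GLCM Diff Average": diff_avg, "GLCM Autocorrelation": autocorr,
        "GLCM Dissimilarity": dissimilarity, "GLCM Cluster Shade": cluster_shade,
        "GLCM Cluster Prominence": cluster_prominence,
    }


def glcm_features(q: QuantizedVolume, mask: np.ndarray | None = None) -> dict[str, float]:
    """Direction- and slice-averaged Haralick features of a quantized VOI."""
    mask = q.mask if mask is None else np.asarray(mask, dtype=bool)
    per_slice: list[dict[str, float]] = []
    for z in range(q.labels.shape[0]):
        if not mask[z].any():
            continue
        per_dir = []
        for d in DIRECTIONS_2D:
            mat = glcm_matrix(q.labels[z], mask[z], d, q.n_levels)
            if mat is not None:
                per_dir.append(_features_from_matrix(mat))
        if per_dir:  # single-voxel slices (no pairs) are skipped
            per_slice.append({k: float(np.mean([f[k] for f in per_dir]))
                              for k in per_dir[0]})
    if not per_slice:
        raise ValueError("no slice contains a valid co-occurring voxel pair")
    return {k: float(np.mean([f[k] for f in per_slice])) for k in per_slice[0]}
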