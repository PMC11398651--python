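"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as plain enumeration (dict counters,
explicit loops, itertools) rather than reusing any code path from the
package, so agreement is evidence of correctness rather than tautology.
"""

from __future__ import annotations

import itertools
from collections import defaultdict

import numpy as np


# ---------------------------------------------------------------- GLCM

def glcm_pairs_bruteforce(labels2d, mask2d, direction):
    """All co-occurring in-mask label pairs (symmetric) by explicit loops."""
    dy, dx = direction
    h, w = labels2d.shape
    counts = defaultdict(float)
    for y in range(h):
        for x in range(w):
            if not mask2d[y, x]:
                continue
            y2, x2 = y + dy, x + dx
            if 0 <= y2 < h and 0 <= x2 < w and mask2d[y2, x2]:
                a, b = labels2d[y, x], labels2d[y2, x2]
                counts[(a, b)] += 1.0
                counts[(b, a)] += 1.0
    return counts


def glcm_matrix_bruteforce(labels2d, mask2d, direction, n_levels):
    counts = glcm_pairs_bruteforce(labels2d, mask2d, direction)
    if not counts:
        return None
    mat = np.zeros((n_levels, n_levels))
    for (a, b), c in counts.items():
        mat[a - 1, b - 1] += c
    return mat / mat.sum()


def glcm_features_bruteforce(p):
    """Haralick features from a normalized co-occurrence matrix, by loops."""
    n = p.shape[0]
    px = [sum(p[i][j] for j in range(n)) for i in range(n)]
    mu = sum((i + 1) * px[i] for i in range(n))
    var = sum((i + 1 - mu) ** 2 * px[i] for i in range(n))
    sig = var ** 0.5

    def log2(v):
        return np.log2(v)

    f = {}
    f["GLCM Contrast"] = sum((i - j) ** 2 * p[i][j] for i in range(n) for j in range(n))
    ac = sum((i + 1) * (j + 1) * p[i][j] for i in range(n) for j in range(n))
    f["GLCM Autocorrelation"] = ac
    f["GLCM Correlation"] = (ac - mu * mu) / var if var > 0 else 1.0
    f["GLCM Sum Squares"] = var
    f["GLCM ASM"] = sum(p[i][j] ** 2 for i in range(n) for j in range(n))
    f["GLCM Entropy"] = -sum(p[i][j] * log2(p[i][j])
                             for i in range(n) for j in range(n) if p[i][j] > 0)
    psum = defaultdict(float)
    pdiff = defaultdict(float)
    for i in range(n):
        for j in range(n):
            psum[i + j + 2] += p[i][j]
            pdiff[abs(i - j)] += p[i][j]
    f["GLCM Sum Entropy"] = -sum(v * log2(v) for v in psum.values() if v > 0)
    f["GLCM Diff Entropy"] = -sum(v * log2(v) for v in pdiff.values() if v > 0)
    da = sum(k * v for k, v in pdiff.items())
    f["GLCM Diff Average"] = da
    f["GLCM Diff Variance"] = sum((k - da) ** 2 * v for k, v in pdiff.items())
    sa = sum(k * v for k, v in psum.items())
    f["GLCM Sum Average"] = sa
    f["GLCM Sum Variance"] = sum((k - sa) ** 2 * v for k, v in psum.items())
    f["GLCM IDM"] = sum(p[i][j] / (1 + (i - j) ** 2) for i in range(n) for j in range(n))
    f["GLCM Homogeneity"] = sum(p[i][j] / (1 + abs(i - j)) for i in range(n) for j in range(n))
    f["GLCM Cluster Tendency"] = sum((i + j + 2 - 2 * mu) ** 2 * p[i][j]
                                     for i in range(n) for j in range(n))
    f["GLCM Cluster Shade"] = sum((i + j + 2 - 2 * mu) ** 3 * p[i][j]
                                  for i in range(n) for j in range(n))
    f["GLCM Cluster Prominence"] = sum((i + j + 2 - 2 * mu) ** 4 * p[i][j]
                                       for i in range(n) for j in range(n))
    f["GLCM Dissimilarity"] = sum(abs(i - j) * p[i][j] for i in range(n) for j in range(n))
    f["GLCM Max Prob"] = max(p[i][j] for i in range(n) for j in range(n))
    hx = -sum(v * log2(v) for v in px if v > 0)
    hxy = f["GLCM Entropy"]
    hxy1 = -sum(p[i][j] * log2(px[i] * px[j])
                for i in range(n) for j in range(n) if p[i][j] > 0 and px[i] * px[j] > 0)
    hxy2 = -sum(px[i] * px[j] * log2(px[i] * px[j])
                for i in range(n) for j in range(n) if px[i] * px[j] > 0)
    f["GLCM IMC1"] = (hxy - hxy1) / hx if hx > 0 else 0.0
    f["GLCM IMC2"] = (max(0.0, 1 - np.exp(-2 * (hxy2 - hxy)))) ** 0.5
    occupied = sum(1 for v in px if v > 0)
    if occupied > 1:
        q = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                q[i, j] = sum(p[i][k] * p[j][k] / (px[i] * px[k])
                              for k in range(n) if px[i] > 0 and px[k] > 0)
        ev = sorted(np.real(np.linalg.eigvals(q)))
        f["GLCM MCC"] = max(0.0, ev[-2]) ** 0.5
    else:
        f["GLCM MCC"] = 1.0
    return f


# ---------------------------------------------------------------- run length

def runs_bruteforce(labels2d, mask2d, direction):
    """Every maximal in-mask run as (gray level, length), by line walking."""
    h, w = labels2d.shape
    dy, dx = direction
    if (dy, dx) == (0, 1):
        starts = [(y, 0) for y in range(h)]
    elif (dy, dx) == (1, 0):
        starts = [(0, x) for x in range(w)]
    elif (dy, dx) == (1, 1):
        starts = [(0, x) for x in range(w)] + [(y, 0) for y in range(1, h)]
    elif (dy, dx) == (1, -1):
        starts = [(0, x) for x in range(w)] + [(y, w - 1) for y in range(1, h)]
    runs = []
    for y0, x0 in starts:
        line = []
        y, x = y0, x0
        while 0 <= y < h and 0 <= x < w:
            line.append((labels2d[y, x], mask2d[y, x]))
            y, x = y + dy, x + dx
        i = 0
        while i < len(line):
            v, m = line[i]
            if not m:
                i += 1
                continue
            j = i
            while j + 1 < len(line) and line[j + 1] == (v, True):
                j += 1
            runs.append((int(v), j - i + 1))
            i = j + 1
    return runs


def run_length_features_bruteforce(runs, n_voxels):
    nr = len(runs)
    f = {
        "RSR Emphasis": sum(1 / l**2 for _, l in runs) / nr,
        "RLR Emphasis": sum(l**2 for _, l in runs) / nr,
        "RHGLR Emphasis": sum(g**2 for g, _ in runs) / nr,
        "RLGLR Emphasis": sum(1 / g**2 for g, _ in runs) / nr,
        "RSRLGL Emphasis": sum(1 / (g**2 * l**2) for g, l in runs) / nr,
        "RSRHGL Emphasis": sum(g**2 / l**2 for g, l in runs) / nr,
        "RLRHGL Emphasis": sum(g**2 * l**2 for g, l in runs) / nr,
        "RLRLGL Emphasis": sum(l**2 / g**2 for g, l in runs) / nr,
        "Run Percentage": nr / n_voxels,
    }
    by_g = defaultdict(int)
    by_l = defaultdict(int)
    for g, l in runs:
        by_g[g] += 1
        by_l[l] += 1
    f["RGL Uniformity"] = sum(c**2 for c in by_g.values()) / nr
    f["RPL Uniformity"] = sum(c**2 for c in by_l.values()) / nr
    return f


# ---------------------------------------------------------------- GTDM

def gtdm_features_bruteforce(labels, mask):
    """Amadasun-King features by per-voxel loops over all slices."""
    nl = int(labels[mask].max())
    s = [0.0] * (nl + 1)
    cnt = [0] * (nl + 1)
    Z, H, W = labels.shape
    for z in range(Z):
        for y in range(H):
            for x in range(W):
                if not mask[z, y, x]:
                    continue
                nbrs = [labels[z, yy, xx]
                        for yy in range(max(0, y - 1), min(H, y + 2))
                        for xx in range(max(0, x - 1), min(W, x + 2))
                        if (yy, xx) != (y, x) and mask[z, yy, xx]]
                if not nbrs:
                    continue
                lev = int(labels[z, y, x])
                s[lev] += abs(lev - sum(nbrs) / len(nbrs))
                cnt[lev] += 1
    N = sum(cnt)
    assert N > 0
    p = [c / N for c in cnt]
    present = [i for i in range(nl + 1) if cnt[i] > 0]
    ngp = len(present)
    ps = sum(p[i] * s[i] for i in present)
    ssum = sum(s)
    out = {"GTDM Coarseness": 1.0 / ps if ps > 0 else 0.0}
    out["GTDM Contrast"] = (sum(p[i] * p[j] * (i - j) ** 2
                                for i in present for j in present)
                            / (ngp * (ngp - 1)) * (ssum / N)) if ngp > 1 else 0.0
    denom = sum(abs(i * p[i] - j * p[j]) for i in present for j in present)
    out["GTDM Busyness"] = ps / denom if ngp > 1 and denom > 0 and ps > 0 else 0.0
    out["GTDM Complexity"] = (sum(abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
                                  for i in present for j in present) / N) if ngp > 1 else 0.0
    out["GTDM Strength"] = (sum((p[i] + p[j]) * (i - j) ** 2
                                for i in present for j in present) / ssum
                            if ssum > 0 and ngp > 1 else 0.0)
    return out


# ---------------------------------------------------------------- statistics

def ccc_bruteforce(x, y):
    """Lin's coefficient via an independent route (Pearson r and moments)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sx = x.std()          # population
    sy = y.std()
    r = np.corrcoef(x, y)[0, 1]
    denom = sx**2 + sy**2 + (x.mean() - y.mean()) ** 2
    if denom == 0:
        return 1.0
    return 2 * r * sx * sy / denom


def _midranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def wilcoxon_exact_bruteforce(values, groups):
    """Two-sided exact rank-sum p (2 * min tail, capped at 1) by exhaustive
    enumeration of group-label assignments, with its own midrank routine."""
    values = list(values)
    groups = list(groups)
    labs = sorted(set(groups))
    n1 = sum(1 for g in groups if g == labs[0])
    ranks = _midranks(values)
    w_obs = sum(r for r, g in zip(ranks, groups) if g == labs[0])
    ws = [sum(ranks[i] for i in c)
          for c in itertools.combinations(range(len(values)), n1)]
    lo = sum(1 for w in ws if w <= w_obs + 1e-12) / len(ws)
    hi = sum(1 for w in ws if w >= w_obs - 1e-12) / len(ws)
    return min(1.0, 2 * min(lo, hi))


# ---------------------------------------------------------------- pruning

def prune_bruteforce(df, threshold):
    """Stepwise removal rule re-implemented over scipy's Spearman matrix."""
    from scipy.stats import spearmanr

    retained = sorted(df.columns)
    while len(retained) > 1:
        sub = df[retained].values
        if len(retained) == 2:
            rho = np.ones((2, 2))
            r = spearmanr(sub[:, 0], sub[:, 1]).statistic
            rho[0, 1] = rho[1, 0] = 0.0 if np.isnan(r) else r
        else:
            rho = spearmanr(sub).statistic
        rho = np.abs(np.nan_to_num(rho, nan=0.0))
        const = sub.std(axis=0) == 0
        rho[const, :] = 0.0
        rho[:, const] = 0.0
        np.fill_diagonal(rho, 1.0)
        off = rho.copy()
        np.fill_diagonal(off, 0.0)
        if off.max() <= threshold:
            break
        best = None
        for i in range(len(retained)):
            for j in range(i + 1, len(retained)):
                if np.isclose(off[i, j], off.max()):
                    cand = tuple(sorted((retained[i], retained[j])))
                    if best is None or cand < best:
                        best = cand
        a, b = best
        ia, ib = retained.index(a), retained.index(b)
        mean_a = np.mean([rho[ia, k] for k in range(len(retained)) if k != ia])
        mean_b = np.mean([rho[ib, k] for k in range(len(retained)) if k != ib])
        if mean_a > mean_b:
            drop = a
        elif mean_b > mean_a:
            drop = b
        else:
            drop = max(a, b)
        retained.remove(drop)
    return retained
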