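"""Filter-bank response features: Gabor, Laws, LoG and Haar wavelet (DWF).

All filters run per axial slice on the VOI crop in which out-of-mask voxels
were replaced by the in-mask mean (see masks.crop_to_mask), with reflective
padding at the crop edge; responses are then sampled over the requested voxel
set (whole VOI / boundary shell / interior) pooled across slices.

Family conventions:
* Gabor: 4 orientations x 2 frequencies (0.1, 0.3 cycles/voxel), sigma = 2
  voxels; the per-voxel response is the mean magnitude over the bank.
* Laws: 5-tap kernel pairs from L5/E5/S5; every registry pair is zero-mean
  (L5L5 excluded), so a constant image gives zero response. The statistic is
  the signed mean response over the voxel set.
* LoG: Laplacian-of-Gaussian, sigma = 2 mm converted to voxels; "MGI" is the
  mean filtered gray-level intensity over the set; Uniformity and Entropy are
  computed on the 25-HU-binned response.
* DWF: undecimated Haar low-pass cascade per slice; "Z L/LL/LLL" is the sum
  of absolute approximation coefficients after 1/2/3 low-pass applications
  over the set, "Z H/HH/HHH" the corresponding detail (difference) sums.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import gabor_kernel

from ..registry import BIN_WIDTH_HU
from .masks import crop_to_mask, voxel_set

FAMILIES = ("Gabor", "Laws", "LoG", "DWF")

GABOR_FREQUENCIES = (0.1, 0.3)
GABOR_ORIENTATIONS = 4
GABOR_SIGMA = 2.0
LOG_SIGMA_MM = 2.0

_L5 = np.array([1.0, 4.0, 6.0, 4.0, 1.0])
_E5 = np.array([-1.0, -2.0, 0.0, 2.0, 1.0])
_S5 = np.array([-1.0, 0.0, 2.0, 0.0, -1.0])
# Registry mapping "Laws 1..6"; every pair has at least one zero-sum factor.
LAWS_PAIRS = {1: (_L5, _E5), 2: (_E5, _L5), 3: (_L5, _S5),
              4: (_S5, _L5), 5: (_E5, _S5), 6: (_S5, _S5)}

_HAAR = np.array([1.0, 1.0]) / np.sqrt(2.0)


def _gabor_bank():
    kernels = []
    for f in GABOR_FREQUENCIES:
        for k in range(GABOR_ORIENTATIONS):
            theta = np.pi * k / GABOR_ORIENTATIONS
            kernels.append(gabor_kernel(f, theta=theta,
                                        sigma_x=GABOR_SIGMA, sigma_y=GABOR_SIGMA))
    return kernels


_BANK = _gabor_bank()


def _gabor_response(sl: np.ndarray) -> np.ndarray:
    acc = np.zeros_like(sl)
    for k in _BANK:
        re = ndimage.convolve(sl, np.real(k), mode="reflect")
        im = ndimage.convolve(sl, np.imag(k), mode="reflect")
        acc += np.hypot(re, im)
    return acc / len(_BANK)


def _sep_conv(sl: np.ndarray, krow: np.ndarray, kcol: np.ndarray) -> np.ndarray:
    out = ndimage.convolve1d(sl, krow, axis=0, mode="reflect")
    return ndimage.convolve1d(out, kcol, axis=1, mode="reflect")


def _set_stats(prefix: str, resp: dict[str, np.ndarray], sets: dict[str, np.ndarray],
               stat_names=("sum", "Max", "Min", "Mean", "Median", "Std")) -> dict[str, float]:
    """Pooled voxel statistics of a response image over the three voxel sets."""
    out = {}
    for suffix, m in sets.items():
        vals = resp[suffix] if isinstance(resp, dict) else resp
        v = vals[m] if m.any() else np.zeros(1)
        stats = {"sum": float(v.sum()), "Max": float(v.max()), "Min": float(v.min()),
                 "Mean": float(v.mean()), "Median": float(np.median(v)),
                 "Std": float(v.std())}
        for s in stat_names:
            out[f"{prefix} {s} Z{suffix}"] = stats[s]
    return out


def _bin_probs(v: np.ndarray, width: float) -> np.ndarray:
    labels = np.floor((v - v.min()) / width).astype(np.int64)
    counts = np.bincount(labels)
    p = counts[counts > 0] / v.size
    return p


def filter_response_features(vol: np.ndarray, mask: np.ndarray, family: str,
                             spacing=(1.0, 1.0, 1.0)) -> dict[str, float]:
    """Named response statistics of one filter family over the VOI."""
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; valid: {FAMILIES}")
    v, m = crop_to_mask(vol, mask)
    sets = {"": m, " Boundary": voxel_set(m, "boundary"),
            " NoBoundary": voxel_set(m, "interior")}
    empty_interior = not sets[" NoBoundary"].any()

    if family == "Gabor":
        resp = np.stack([_gabor_response(v[z]) for z in range(v.shape[0])])
        out = _set_stats("Gabor", resp, sets)
        return out

    if family == "Laws":
        out = {}
        for k, (kr, kc) in LAWS_PAIRS.items():
            resp = np.stack([_sep_conv(v[z], kr, kc) for z in range(v.shape[0])])
            for suffix, mm in sets.items():
                vals = resp[mm] if mm.any() else np.zeros(1)
                out[f"Laws {k} Z{suffix}"] = float(vals.mean())
        return out

    if family == "LoG":
        sigma_vox = LOG_SIGMA_MM / float(np.mean(spacing[1:]))  # in-plane mm -> voxels
        resp = np.stack([ndimage.gaussian_laplace(v[z], sigma=sigma_vox)
                         for z in range(v.shape[0])])
        whole = resp[m]
        p = _bin_probs(whole, BIN_WIDTH_HU)
        pb = _bin_probs(resp[sets[" Boundary"]], BIN_WIDTH_HU)
        out = {
            "LoG Z MGI": float(whole.mean()),
            "LoG Z Uniformity": float((p ** 2).sum()),
            "LoG Z Entropy": float(-(p * np.log2(p)).sum()),
            "LoG Z MGI Boundary": float(resp[sets[" Boundary"]].mean()),
            "LoG Z MGI NoBoundary": (float(resp[sets[" NoBoundary"]].mean())
                                     if not empty_interior else 0.0),
            "LoG Z Uniformity Boundary": float((pb ** 2).sum()),
            "LoG Z Entropy Boundary": float(-(pb * np.log2(pb)).sum()),
            "LoG Z Std": float(whole.std()),
            "LoG Z Energy": float((whole ** 2).sum()),
        }
        return out

    # DWF: Haar low-pass cascade
    out = {}
    approx = v.copy()
    prev = v.copy()
    for level, band in enumerate(("L", "LL", "LLL"), start=1):
        approx = np.stack([_sep_conv(prev[z], _HAAR, _HAAR) for z in range(v.shape[0])])
        detail = prev - approx
        for suffix, mm in sets.items():
            vals = np.abs(approx[mm]) if mm.any() else np.zeros(1)
            out[f"DWF Z {band}{suffix}"] = float(vals.sum())
        out[f"DWF Z {'H' * level}"] = float(np.abs(detail[m]).sum())
        prev = approx
    return out
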