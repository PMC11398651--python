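"""Fixed-bin-width intensity discretization.

HU values inside the VOI are mapped to integer gray levels with a fixed bin
width (25 HU by default) anchored at the in-mask minimum:

    label(h) = floor((h - min_in_mask) / bin_width) + 1

Anchoring at the minimum makes every quantized-texture feature invariant to
adding a constant HU offset to the volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..registry import BIN_WIDTH_HU


@dataclass
class QuantizedVolume:
    labels: np.ndarray        # int array, full crop shape; 0 outside mask
    mask: np.ndarray          # bool, same shape
    n_levels: int             # number of possible levels (>= max label)
    bin_width: float
    min_in_mask: float

    def in_mask_labels(self) -> np.ndarray:
        return self.labels[self.mask]


def discretize_intensities(vol: np.ndarray, mask: np.ndarray,
                           bin_width: float = BIN_WIDTH_HU) -> QuantizedVolume:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if bin_width <= 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    vol = np.asarray(vol, dtype=np.float64)
    vmin = vol[mask].min()
    labels = np.zeros(vol.shape, dtype=np.int64)
    labels[mask] = np.floor((vol[mask] - vmin) / bin_width).astype(np.int64) + 1
    n_levels = int(labels.max())
    return QuantizedVolume(labels=labels, mask=mask, n_levels=n_levels,
                           bin_width=float(bin_width), min_in_mask=float(vmin))
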