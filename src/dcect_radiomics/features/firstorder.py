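"""First-order intensity statistics over the VOI.

Histogram-based members (Entropy, Uniformity, PeakPosition) use the fixed
25-HU binning anchored at the in-mask minimum; all moments are population
(1/n) moments. Entropy is in bits.
"""

from __future__ import annotations

import numpy as np

from ..registry import BIN_WIDTH_HU


def first_order_features(vol: np.ndarray, mask: np.ndarray,
                         bin_width: float = BIN_WIDTH_HU) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    x = np.asarray(vol, dtype=np.float64)[mask]
    n = x.size
    mean = x.mean()
    var = x.var()          # population
    std = np.sqrt(var)

    labels = np.floor((x - x.min()) / bin_width).astype(np.int64)
    counts = np.bincount(labels)
    p = counts[counts > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p ** 2).sum())
    peak_label = int(np.argmax(counts))
    peak_position = float(x.min() + (peak_label + 0.5) * bin_width)

    q10, q25, q50, q75, q90 = np.percentile(x, [10, 25, 50, 75, 90])
    skew = float(((x - mean) ** 3).mean() / std**3) if std > 0 else 0.0
    kurt = float(((x - mean) ** 4).mean() / std**4 - 3.0) if std > 0 else 0.0

    return {
        "Intensity Mean": float(mean),
        "Intensity Median": float(q50),
        "Intensity Std": float(std),
        "Intensity Variance": float(var),
        "Intensity Energy": float((x ** 2).sum()),
        "Intensity Entropy": entropy,
        "Intensity Uniformity": uniformity,
        "Intensity Mean absolute deviation": float(np.abs(x - mean).mean()),
        "Intensity Root mean square": float(np.sqrt((x ** 2).mean())),
        "Intensity 25percent": float(q25),
        "Intensity 75percent": float(q75),
        "Intensity Maximum": float(x.max()),
        "Intensity Minimum": float(x.min()),
        "Intensity PeakPosition": peak_position,
        "Intensity 10percent": float(q10),
        "Intensity 90percent": float(q90),
        "Intensity Range": float(x.max() - x.min()),
        "Intensity Interquartile range": float(q75 - q25),
        "Intensity Skewness": skew,
        "Intensity Kurtosis": kurt,
        "Intensity Sum": float(x.sum()),
    }
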