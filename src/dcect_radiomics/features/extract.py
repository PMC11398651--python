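"""Full-registry feature extraction: one VOI in, 127 named values out.

Runs every class extractor on the native grid (no resampling), using the
fixed 25-HU binning for quantized-texture classes. Extraction is entirely
deterministic. If an individual class extractor fails on a degenerate VOI its
features are reported as missing (NaN) with a warning; if more than 10% of
the registry would be missing the extraction fails outright.
"""

from __future__ import annotations

import warnings

import numpy as np

from ..registry import BIN_WIDTH_HU, feature_names
from .quantize import discretize_intensities
from .masks import crop_to_mask
from .firstorder import first_order_features
from .glcm import glcm_features
from .runlength import run_length_features
from .gtdm import gtdm_features
from .filters import filter_response_features, FAMILIES
from .sigmoid import sigmoid_boundary_features
from .misc import misc_texture_features

FeatureVector = dict  # ordered name -> value map with exactly 127 keys


class FeatureExtractionError(RuntimeError):
    pass


def extract_feature_vector(vol: np.ndarray, mask: np.ndarray,
                           spacing=(1.0, 1.0, 1.0),
                           bin_width: float = BIN_WIDTH_HU) -> FeatureVector:
    vol = np.asarray(vol, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if vol.shape != mask.shape:
        raise ValueError(f"volume shape {vol.shape} != mask shape {mask.shape}")
    if not mask.any():
        raise ValueError("mask is empty")
    if not np.isfinite(vol[mask]).all():
        raise ValueError("non-finite HU values inside the mask")

    v, m = crop_to_mask(vol, mask)
    v_raw, _ = crop_to_mask(vol, mask, fill=False)  # sigmoid needs the real edge
    q = discretize_intensities(v, m, bin_width)

    values: dict[str, float] = {}

    def run(fn, *args, **kw):
        try:
            values.update(fn(*args, **kw))
        except Exception as exc:  # degenerate VOI for this class
            warnings.warn(f"{fn.__name__} failed: {exc}; features set to missing")

    run(first_order_features, v, m, bin_width)
    run(glcm_features, q)
    run(run_length_features, q)
    run(gtdm_features, q)
    for family in FAMILIES:
        run(filter_response_features, v, m, family, spacing)
    run(sigmoid_boundary_features, v_raw, m)
    run(misc_texture_features, v, m)

    names = feature_names()
    missing = [n for n in names if n not in values]
    if len(missing) > 0.10 * len(names):
        raise FeatureExtractionError(
            f"{len(missing)} of {len(names)} features missing: {missing[:5]}...")
    out = {n: float(values.get(n, np.nan)) for n in names}
    return out
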