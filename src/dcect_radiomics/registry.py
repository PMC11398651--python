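"""The fixed registry of 127 named radiomic features.

The registry is the single source of truth for feature names, their class,
the voxel set they are computed on (whole VOI, boundary shell, or interior)
and the filter parameters that define them. Feature names follow the study's
printed conventions ("GLCM Contrast", "RSRLGL Emphasis", "Gabor Mean Z
Boundary", ...); the published tables name about 70 of the 127 features, and
each class is filled to its documented count with conventional members of the
same family, flagged ``reconstructed`` in the manifest.

Naming conventions:
* "Z" marks per-slice (axial) 2D computation aggregated across slices;
* "Boundary" = the one-voxel rim shell of the VOI, "NoBoundary" = its
  interior, no suffix = the whole VOI;
* run-length acronyms: RSR = Run Short Run, RLR = Run Long Run, RGL = Run
  Gray Level, RPL = Run Primitive Length, RHGLR/RLGLR = Run High/Low Gray
  Level Run, and compounds such as RSRLGL = Run Short Run Low Gray Level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

BIN_WIDTH_HU = 25.0  # fixed intensity bin width; binning re-anchors at the in-mask minimum

VOXEL_SETS = ("whole", "boundary", "interior")


@dataclass(frozen=True)
class FeatureDef:
    name: str
    feature_class: str
    voxel_set: str = "whole"
    printed: bool = True          # named verbatim in the published tables
    params: tuple = ()


def _suffix_set(suffix: str) -> str:
    return {"": "whole", " Boundary": "boundary", " NoBoundary": "interior"}[suffix]


def _build() -> list[FeatureDef]:
    defs: list[FeatureDef] = []

    first_order_printed = [
        "Mean", "Median", "Std", "Variance", "Energy", "Entropy", "Uniformity",
        "Mean absolute deviation", "Root mean square", "25percent", "75percent",
        "Maximum", "Minimum", "PeakPosition",
    ]
    first_order_extra = [
        "10percent", "90percent", "Range", "Interquartile range", "Skewness",
        "Kurtosis", "Sum",
    ]
    for n in first_order_printed:
        defs.append(FeatureDef(f"Intensity {n}", "First Order Statistics"))
    for n in first_order_extra:
        defs.append(FeatureDef(f"Intensity {n}", "First Order Statistics", printed=False))

    glcm_printed = [
        "Contrast", "Correlation", "Sum Squares", "ASM", "Entropy", "Sum Entropy",
        "Diff Entropy", "Diff Variance", "IDM", "Homogeneity", "Cluster Tendency",
        "IMC1", "IMC2", "MCC", "Max Prob",
    ]
    glcm_extra = [
        "Sum Average", "Sum Variance", "Diff Average", "Autocorrelation",
        "Dissimilarity", "Cluster Shade", "Cluster Prominence",
    ]
    for n in glcm_printed:
        defs.append(FeatureDef(f"GLCM {n}", "GLCM"))
    for n in glcm_extra:
        defs.append(FeatureDef(f"GLCM {n}", "GLCM", printed=False))

    rl_printed = [
        "RSR Emphasis", "RLR Emphasis", "RGL Uniformity", "RPL Uniformity",
        "RHGLR Emphasis", "RLGLR Emphasis", "RSRLGL Emphasis", "RSRHGL Emphasis",
        "RLRHGL Emphasis", "RLRLGL Emphasis",
    ]
    for n in rl_printed:
        defs.append(FeatureDef(n, "Run Length"))
    defs.append(FeatureDef("Run Percentage", "Run Length", printed=False))

    defs.append(FeatureDef("GTDM Strength", "GTDM"))
    defs.append(FeatureDef("GTDM Complexity", "GTDM"))
    for n in ("Coarseness", "Busyness", "Contrast"):
        defs.append(FeatureDef(f"GTDM {n}", "GTDM", printed=False))

    for stat in ("sum", "Max", "Min", "Mean", "Median", "Std"):
        for suffix in ("", " Boundary", " NoBoundary"):
            printed = stat != "Std" and suffix != " NoBoundary"
            defs.append(FeatureDef(f"Gabor {stat} Z{suffix}", "Gabor",
                                   voxel_set=_suffix_set(suffix), printed=printed,
                                   params=("orientations=4", "frequencies=0.1,0.3", "sigma=2vox")))

    for k in range(1, 7):
        for suffix in (" Boundary", " NoBoundary", ""):
            defs.append(FeatureDef(f"Laws {k} Z{suffix}", "LAW filter",
                                   voxel_set=_suffix_set(suffix), printed=(suffix != ""),
                                   params=(f"kernel_pair=laws{k}",)))

    log_defs = [
        ("LoG Z Uniformity", "whole", True), ("LoG Z Entropy", "whole", True),
        ("LoG Z MGI", "whole", True),
        ("LoG Z Uniformity Boundary", "boundary", False),
        ("LoG Z Entropy Boundary", "boundary", False),
        ("LoG Z MGI Boundary", "boundary", False),
        ("LoG Z MGI NoBoundary", "interior", False),
        ("LoG Z Std", "whole", False), ("LoG Z Energy", "whole", False),
    ]
    for name, vset, printed in log_defs:
        defs.append(FeatureDef(name, "LOG feature", voxel_set=vset, printed=printed,
                               params=("sigma=2mm",)))

    for band in ("L", "LL", "LLL"):
        for suffix in ("", " Boundary", " NoBoundary"):
            defs.append(FeatureDef(f"DWF Z {band}{suffix}", "Discrete Wavelet Transform",
                                   voxel_set=_suffix_set(suffix), printed=(suffix == ""),
                                   params=("wavelet=haar", f"level={len(band)}")))
    for band in ("H", "HH", "HHH"):
        defs.append(FeatureDef(f"DWF Z {band}", "Discrete Wavelet Transform",
                               printed=False, params=("wavelet=haar", f"level={len(band)}")))

    for p in ("Amplitude", "Offset"):
        for s in ("Mean", "Std"):
            defs.append(FeatureDef(f"Sigmoid {p} {s}", "Sigmoid Feature",
                                   voxel_set="boundary", params=("profile_len=11",)))
    for s in ("Mean", "Std"):
        defs.append(FeatureDef(f"Sigmoid Width {s}", "Sigmoid Feature",
                               voxel_set="boundary", printed=False, params=("profile_len=11",)))

    defs.append(FeatureDef("Edge Frequency", "Edge Frequency"))
    defs.append(FeatureDef("Edge Frequency Boundary", "Edge Frequency",
                           voxel_set="boundary", printed=False))
    defs.append(FeatureDef("Edge Frequency NoBoundary", "Edge Frequency",
                           voxel_set="interior", printed=False))
    defs.append(FeatureDef("Fractal Dimension", "Fractal Dimension"))
    defs.append(FeatureDef("Spatial Correlation", "Spatial correlation",
                           params=("statistic=2*(1+lag1_autocorr)",)))
    return defs


FEATURE_REGISTRY: list[FeatureDef] = _build()
assert len(FEATURE_REGISTRY) == 127, len(FEATURE_REGISTRY)
assert len({d.name for d in FEATURE_REGISTRY}) == 127

_BY_NAME = {d.name: d for d in FEATURE_REGISTRY}


def feature_names() -> list[str]:
    """All 127 feature names in registry (output) order."""
    return [d.name for d in FEATURE_REGISTRY]


def feature_def(name: str) -> FeatureDef:
    return _BY_NAME[name]


def registry_manifest() -> list[dict]:
    """JSON-serializable manifest of the full registry."""
    out = []
    for d in FEATURE_REGISTRY:
        rec = asdict(d)
        rec["params"] = list(d.params)
        out.append(rec)
    return out


def write_manifest(path) -> None:
    with open(path, "w") as fh:
        json.dump({"bin_width_hu": BIN_WIDTH_HU, "n_features": 127,
                   "features": registry_manifest()}, fh, indent=1)


def normalize_feature_name(raw: str) -> str | None:
    """Map an external header (underscore/punctuation variants, stray
    trailing separators) onto a registry name, or None if no match."""
    key = " ".join(raw.replace("_", " ").split()).strip().lower()
    for d in FEATURE_REGISTRY:
        if " ".join(d.name.split()).lower() == key:
            return d.name
    return None
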