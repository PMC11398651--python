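"""Volume and mask I/O: NIfTI read/write and DICOM-series reading.

Volumes are stored one file per sequence as ``{patient}_{phase}_{seqindex}``
NIfTI with the voxel spacing in the affine; masks use matching geometry.
Geometry mismatches beyond 1e-3 mm between a volume and its mask are a hard
error.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import nibabel as nib

GEOMETRY_TOL_MM = 1e-3


def write_nifti(path, array: np.ndarray, spacing) -> None:
    affine = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
    # store as (x, y, z) per NIfTI convention; our arrays are (z, y, x)
    img = nib.Nifti1Image(np.asarray(array).transpose(2, 1, 0).astype(np.float32), affine)
    nib.save(img, str(path))


def read_nifti(path):
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).transpose(2, 1, 0).astype(np.float64)
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return data, spacing


def read_dicom_series(directory):
    """Read a DICOM series directory into a (z, y, x) array + spacing (mm)."""
    import SimpleITK as sitk

    reader = sitk.ImageSeriesReader()
    files = reader.GetGDCMSeriesFileNames(str(directory))
    if not files:
        raise ValueError(f"no DICOM series found in {directory}")
    reader.SetFileNames(files)
    img = reader.Execute()
    data = sitk.GetArrayFromImage(img).astype(np.float64)  # (z, y, x)
    sp = img.GetSpacing()  # (x, y, z)
    return data, (float(sp[2]), float(sp[1]), float(sp[0]))


def check_geometry(vol_shape, vol_spacing, mask_shape, mask_spacing) -> None:
    if tuple(vol_shape) != tuple(mask_shape):
        raise ValueError(f"shape mismatch: volume {vol_shape} vs mask {mask_shape}")
    d = np.abs(np.asarray(vol_spacing) - np.asarray(mask_spacing))
    if (d > GEOMETRY_TOL_MM).any():
        raise ValueError(f"spacing mismatch beyond {GEOMETRY_TOL_MM} mm: "
                         f"{vol_spacing} vs {mask_spacing}")


def write_case(case, out_dir) -> list[dict]:
    """Write one phantom case's volumes and masks; return manifest rows."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    s = case.series
    for vol, phase, k in zip(s.volumes, s.phases, s.seq_indices):
        vp = out_dir / f"{case.patient_id}_{phase}_{k:02d}.nii.gz"
        write_nifti(vp, vol, s.spacing)
        rows.append({"patient_id": case.patient_id, "phase": phase, "seq_index": k,
                     "path": str(vp), "grade": case.grade, "observer": ""})
    for obs, mask in (("R1", case.observer1_mask), ("R2", case.observer2_mask)):
        mp = out_dir / f"{case.patient_id}_mask_{obs}.nii.gz"
        write_nifti(mp, mask.astype(np.uint8), s.spacing)
        rows.append({"patient_id": case.patient_id, "phase": "", "seq_index": -1,
                     "path": str(mp), "grade": case.grade, "observer": obs})
    return rows
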