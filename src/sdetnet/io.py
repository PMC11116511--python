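"""Volumetric I/O: NIfTI read/write and read-only DICOM series import.

NIfTI (.nii / .nii.gz) is the primary on-disk format; the affine carries the
voxel spacing on its diagonal.  DICOM import stacks a series along axis 0
(the axial axis) after validating consistent orientation and in-plane
geometry.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .core import BinaryMask, Volume


def save_volume(vol: Volume, path: str | Path) -> None:
    affine = np.diag(list(vol.spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), affine),
             str(path))


def load_volume(path: str | Path) -> Volume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data, spacing)


def save_mask(mask: BinaryMask, path: str | Path) -> None:
    affine = np.diag(list(mask.spacing) + [1.0])
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), affine), str(path))


def load_mask(path: str | Path) -> BinaryMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return BinaryMask(data.astype(np.uint8), spacing)


def load_dicom_series(directory: str | Path) -> Volume:
    """Import a single-frame DICOM series as a Volume (slices -> axis 0).

    Slices are ordered by ImagePositionPatient along the slice normal (or by
    InstanceNumber as a fallback).  Series with inconsistent orientation,
    pixel spacing, or in-plane shape are rejected.
    """
    import pydicom

    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        raise ValueError(f"no .dcm files in {directory}")
    slices = [pydicom.dcmread(str(p)) for p in files]

    ref = slices[0]
    orientation = getattr(ref, "ImageOrientationPatient", None)
    pixel_spacing = [float(v) for v in ref.PixelSpacing]
    shape = (int(ref.Rows), int(ref.Columns))
    for ds in slices[1:]:
        if getattr(ds, "ImageOrientationPatient", None) != orientation:
            raise ValueError("inconsistent slice orientations in DICOM series")
        if [float(v) for v in ds.PixelSpacing] != pixel_spacing:
            raise ValueError("inconsistent pixel spacing in DICOM series")
        if (int(ds.Rows), int(ds.Columns)) != shape:
            raise ValueError("inconsistent slice dimensions in DICOM series")

    def sort_key(ds):
        pos = getattr(ds, "ImagePositionPatient", None)
        if pos is not None:
            return float(pos[2])
        return int(getattr(ds, "InstanceNumber", 0))

    slices.sort(key=sort_key)
    data = np.stack([ds.pixel_array.astype(np.float32) for ds in slices], axis=0)

    if len(slices) > 1:
        p0, p1 = sort_key(slices[0]), sort_key(slices[1])
        dz = abs(p1 - p0) or 1.0
    else:
        dz = float(getattr(ref, "SliceThickness", 1.0) or 1.0)
    return Volume(data, (dz, pixel_spacing[0], pixel_spacing[1]))
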