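"""Reading and writing CT volumes and masks.

Supported inputs: NIfTI (.nii/.nii.gz), MetaImage (.mha/.mhd) and DICOM
series directories.  Values must be calibrated Hounsfield units; for DICOM
the rescale slope/intercept is applied.  Spacing always comes from header
metadata — a missing or non-positive spacing is a hard error, never a
silent default, because every downstream voxel count depends on it.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
import SimpleITK as sitk

from .errors import VolumeReadError
from .geometry import CTVolume

__all__ = ["read_volume", "write_volume", "write_mask", "read_seed_sidecar"]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_METAIMAGE_SUFFIXES = (".mha", ".mhd")


def _from_sitk(image: sitk.Image) -> CTVolume:
    # sitk arrays are (z, y, x); our convention is (x, y, z)
    values = sitk.GetArrayFromImage(image).astype(np.float64).transpose(2, 1, 0)
    spacing = tuple(float(s) for s in image.GetSpacing())
    if any(s <= 0 for s in spacing):
        raise VolumeReadError(f"non-positive voxel spacing in header: {spacing}")
    return CTVolume(values=values, spacing=spacing)  # type: ignore[arg-type]


def _raw_nifti_zooms(path: Path) -> tuple[float, float, float]:
    # nibabel and ITK silently repair invalid pixdims on load; inspect the
    # on-disk header so a missing spacing is an error, not a default of 1.0
    import gzip

    opener = gzip.open if path.name.lower().endswith(".gz") else open
    with opener(path, "rb") as fh:  # type: ignore[operator]
        header = nib.Nifti1Header.from_fileobj(fh, check=False)
    return tuple(float(z) for z in header["pixdim"][1:4])  # type: ignore[return-value]


def _read_nifti(path: Path) -> CTVolume:
    raw_zooms = _raw_nifti_zooms(path)
    if any(z <= 0 for z in raw_zooms):
        raise VolumeReadError(f"NIfTI header has missing or non-positive spacing: {raw_zooms}")
    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim != 3:
        raise VolumeReadError(f"expected a 3-D volume, got shape {data.shape}")
    return CTVolume(values=data, spacing=zooms)


def _validate_dicom_series(files: list[str]) -> None:
    orientations = []
    for f in files:
        ds = pydicom.dcmread(f, stop_before_pixels=True)
        if "PixelSpacing" not in ds:
            raise VolumeReadError(f"DICOM slice {f} has no PixelSpacing tag")
        if "ImageOrientationPatient" in ds:
            orientations.append(tuple(round(float(v), 6) for v in ds.ImageOrientationPatient))
    if len(set(orientations)) > 1:
        raise VolumeReadError("mixed-orientation DICOM series: slices do not share one ImageOrientationPatient")


def _read_dicom_series(directory: Path) -> CTVolume:
    reader = sitk.ImageSeriesReader()
    files = reader.GetGDCMSeriesFileNames(str(directory))
    if not files:
        raise VolumeReadError(f"no DICOM series found in {directory}")
    _validate_dicom_series(list(files))
    if len(files) == 1:
        ds = pydicom.dcmread(files[0])
        sy, sx = (float(v) for v in ds.PixelSpacing)  # row spacing, column spacing
        sz = float(getattr(ds, "SpacingBetweenSlices", getattr(ds, "SliceThickness", 0.0)) or 0.0)
        if sz <= 0:
            raise VolumeReadError("single-slice DICOM series without SliceThickness: z spacing unknown")
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        hu = slope * arr + intercept
        # pixel_array is (row, col) = (y, x); transpose to (x, y) and add z axis
        return CTVolume(values=hu.T[:, :, np.newaxis], spacing=(sx, sy, sz))
    reader.SetFileNames(files)
    image = reader.Execute()  # applies rescale slope/intercept
    return _from_sitk(image)


def read_volume(path: str | os.PathLike) -> CTVolume:
    """Read a CT volume in HU from NIfTI, MetaImage or a DICOM series directory.

    The format is inferred from the path: a directory is treated as a DICOM
    series, otherwise the file suffix decides.
    """
    p = Path(path)
    if not p.exists():
        raise VolumeReadError(f"no such file or directory: {p}")
    if p.is_dir():
        return _read_dicom_series(p)
    name = p.name.lower()
    if name.endswith(_NIFTI_SUFFIXES):
        return _read_nifti(p)
    if name.endswith(_METAIMAGE_SUFFIXES):
        return _from_sitk(sitk.ReadImage(str(p)))
    raise VolumeReadError(f"unrecognised volume format: {p.name}")


def _to_nifti(values: np.ndarray, spacing: tuple[float, float, float]) -> nib.Nifti1Image:
    affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    return nib.Nifti1Image(values, affine)


def write_volume(volume: CTVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI (values in HU, spacing in the affine)."""
    nib.save(_to_nifti(volume.values.astype(np.float32), volume.spacing), str(path))


def write_mask(labels: np.ndarray, spacing: tuple[float, float, float], path: str | os.PathLike) -> None:
    """Write an integer label mask as NIfTI."""
    nib.save(_to_nifti(np.asarray(labels, dtype=np.uint8), spacing), str(path))


def read_seed_sidecar(path: str | os.PathLike) -> tuple[int, int, int]:
    """Read a per-scan seed point from a JSON sidecar ({"seed": [i, j, k]})."""
    with open(path) as fh:
        data = json.load(fh)
    seed = data["seed"]
    if len(seed) != 3:
        raise VolumeReadError(f"seed sidecar must hold three integer indices, got {seed}")
    return tuple(int(v) for v in seed)  # type: ignore[return-value]
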