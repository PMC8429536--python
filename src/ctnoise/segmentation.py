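"""Tracheal air segmentation and the ground-truth noise level.

The lumen of the caudal trachea and proximal bronchi is segmented inside a
61 × 61 × 61 voxel crop by 26-connected region growing from a user seed
among voxels below an air threshold (default −500 HU, which separates air
at ≈ −1000 HU from wall and parenchyma at both clinically relevant noise
levels).  The crop is centered on the seed, clamped at the image borders
and zero-padded back to 61³ so its size is invariant.

The ground-truth noise is the sample SD of the HU values inside the mask
after a one-voxel morphological erosion (3×3×3 cube structuring element),
which strips the boundary shell affected by partial-volume blending with
the airway wall.

The carina ridge — the landmark above which measurements are placed — is
found as the most caudal axial slice whose lumen cross-section is a single
8-connected component while the next caudal slice holds two or more (the
trachea/main-bronchi transition).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import (
    NoBifurcationError,
    PlacementError,
    SeedPointError,
    SegmentationLeakWarning,
    UndefinedStatisticError,
)
from .geometry import CTVolume, VoxelIndex

__all__ = [
    "AirwayMask",
    "CarinaLandmark",
    "CROP_SIZE",
    "segment_airway",
    "true_noise",
    "detect_carina",
    "measurement_center",
    "mask_labels",
]

CROP_SIZE = 61
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class AirwayMask:
    """Binary lumen segmentation within the analysis crop.

    ``crop_origin`` is the full-volume index of crop voxel (0, 0, 0); it can
    be negative when the crop was clamped at an image border and padded.
    ``mask_full`` is the grown region before erosion (the containment
    reference for the exclusion rule); ``mask_eroded`` is the ground-truth
    region after the one-voxel erosion.
    """

    crop_origin: VoxelIndex
    mask_full: np.ndarray
    mask_eroded: np.ndarray

    def __post_init__(self) -> None:
        for name in ("mask_full", "mask_eroded"):
            arr = np.asarray(getattr(self, name), dtype=bool)
            object.__setattr__(self, name, arr)
            if arr.shape != (CROP_SIZE,) * 3:
                raise ValueError(f"{name} must be {CROP_SIZE}^3, got {arr.shape}")
        if np.any(self.mask_eroded & ~self.mask_full):
            raise ValueError("mask_eroded must be a subset of mask_full")
        object.__setattr__(self, "crop_origin", VoxelIndex(*self.crop_origin))

    def to_crop(self, index: VoxelIndex) -> VoxelIndex:
        """Map a full-volume voxel index into crop coordinates."""
        return VoxelIndex(*(int(c) - int(o) for c, o in zip(index, self.crop_origin)))

    def to_full(self, index: VoxelIndex) -> VoxelIndex:
        """Map a crop voxel index into full-volume coordinates."""
        return VoxelIndex(*(int(c) + int(o) for c, o in zip(index, self.crop_origin)))

    def contains_full(self, voxels: np.ndarray) -> np.ndarray:
        """Whether each full-volume (i, j, k) row lies inside ``mask_full``.

        Voxels outside the crop are outside the segmentation by definition.
        """
        v = np.asarray(voxels, dtype=np.int64) - np.asarray(self.crop_origin, dtype=np.int64)
        inside = np.all((v >= 0) & (v < CROP_SIZE), axis=1)
        out = np.zeros(len(v), dtype=bool)
        if inside.any():
            vi = v[inside]
            out[inside] = self.mask_full[vi[:, 0], vi[:, 1], vi[:, 2]]
        return out


@dataclass(frozen=True)
class CarinaLandmark:
    """The carina ridge: axial slice index and a ridge point, in crop coords."""

    ridge_slice: int
    ridge_point: VoxelIndex

    def __post_init__(self) -> None:
        object.__setattr__(self, "ridge_point", VoxelIndex(*self.ridge_point))


def _crop_window(volume: CTVolume, seed: VoxelIndex) -> tuple[VoxelIndex, np.ndarray]:
    """Extract the 61³ crop centered on the seed, zero-padding past borders."""
    half = CROP_SIZE // 2
    origin = np.asarray(seed, dtype=np.int64) - half
    crop = np.zeros((CROP_SIZE,) * 3, dtype=np.float64)
    lo_src = np.maximum(origin, 0)
    hi_src = np.minimum(origin + CROP_SIZE, np.asarray(volume.shape))
    lo_dst = lo_src - origin
    hi_dst = hi_src - origin
    crop[lo_dst[0]:hi_dst[0], lo_dst[1]:hi_dst[1], lo_dst[2]:hi_dst[2]] = volume.values[
        lo_src[0]:hi_src[0], lo_src[1]:hi_src[1], lo_src[2]:hi_src[2]
    ]
    return VoxelIndex(*(int(v) for v in origin)), crop


def segment_airway(volume: CTVolume, seed: VoxelIndex, hu_threshold: float = -500.0) -> AirwayMask:
    """Segment the tracheal air around a seed point.

    26-connected region growing from ``seed`` among voxels with
    HU < ``hu_threshold``, restricted to the 61³ crop centered on the seed.
    Raises :class:`SeedPointError` if the seed itself is not air; emits a
    :class:`SegmentationLeakWarning` if the grown region touches all six
    crop faces, which suggests a leak out of the airway.
    """
    seed = VoxelIndex(*seed)
    if not volume.contains(seed):
        raise SeedPointError(f"seed {tuple(seed)} outside grid {volume.shape}")
    if volume.values[seed] >= hu_threshold:
        raise SeedPointError(
            f"seed voxel has {volume.values[seed]:.0f} HU, not below the air threshold {hu_threshold:.0f} HU"
        )
    origin, crop = _crop_window(volume, seed)
    air = crop < hu_threshold
    labels, _ = ndimage.label(air, structure=_STRUCT_26)
    seed_crop = tuple(np.asarray(seed) - np.asarray(origin))
    mask_full = labels == labels[seed_crop]
    faces_touched = sum(
        bool(mask_full.take(idx, axis=ax).any()) for ax in range(3) for idx in (0, CROP_SIZE - 1)
    )
    if faces_touched == 6:
        warnings.warn(
            "segmented region touches all six crop faces; the segmentation may have leaked",
            SegmentationLeakWarning,
            stacklevel=2,
        )
    mask_eroded = ndimage.binary_erosion(mask_full, structure=_STRUCT_26)
    return AirwayMask(crop_origin=origin, mask_full=mask_full, mask_eroded=mask_eroded)


def true_noise(volume: CTVolume, mask: AirwayMask) -> float:
    """Ground-truth noise: sample SD of HU over the eroded lumen mask."""
    idx = np.argwhere(mask.mask_eroded)
    if len(idx) < 2:
        raise UndefinedStatisticError("eroded mask has fewer than 2 voxels; SD undefined")
    full = idx + np.asarray(mask.crop_origin, dtype=np.int64)
    in_grid = np.all((full >= 0) & (full < np.asarray(volume.shape)), axis=1)
    values = volume.values[full[in_grid, 0], full[in_grid, 1], full[in_grid, 2]]
    if len(values) < 2:
        raise UndefinedStatisticError("fewer than 2 eroded-mask voxels lie inside the image grid")
    return float(np.std(values, ddof=1))


def _slice_components(mask_slice: np.ndarray) -> tuple[int, np.ndarray]:
    """8-connected component count and label image of one axial cross-section."""
    labels, n = ndimage.label(mask_slice, structure=np.ones((3, 3), dtype=bool))
    return n, labels


def detect_carina(mask: AirwayMask, cranial_direction: int = +1) -> CarinaLandmark:
    """Locate the carina ridge in the airway mask.

    ``cranial_direction`` is +1 when the axial index k increases toward the
    head (the package convention) and −1 for flipped volumes.  The ridge is
    the most caudal slice with a single 8-connected lumen component whose
    caudal neighbor slice has two or more (the bifurcation into the main
    bronchi).  The ridge point is the in-plane centroid of that single
    component, rounded to the nearest voxel; both are in crop coordinates.
    """
    if cranial_direction not in (+1, -1):
        raise ValueError("cranial_direction must be +1 or -1")
    m = mask.mask_full
    counts = np.empty(CROP_SIZE, dtype=np.int64)
    for k in range(CROP_SIZE):
        counts[k], _ = _slice_components(m[:, :, k])
    ks = range(CROP_SIZE) if cranial_direction == +1 else range(CROP_SIZE - 1, -1, -1)
    for k in ks:
        caudal = k - cranial_direction
        if not (0 <= caudal < CROP_SIZE):
            continue
        if counts[k] == 1 and counts[caudal] >= 2:
            _, labels = _slice_components(m[:, :, k])
            ci, cj = ndimage.center_of_mass(labels == 1)
            return CarinaLandmark(
                ridge_slice=int(k),
                ridge_point=VoxelIndex(int(round(ci)), int(round(cj)), int(k)),
            )
    raise NoBifurcationError("no axial 2-to-1 component transition found; mask holds no bifurcation")


def measurement_center(
    mask: AirwayMask,
    landmark: CarinaLandmark,
    height_cm: float,
    spacing: tuple[float, float, float],
    cranial_direction: int = +1,
) -> VoxelIndex:
    """Isocenter of the measurement shapes at a height above the carina.

    The target slice is ``ridge_slice`` plus ``round(10·height_cm / z_spacing)``
    slices toward the cranial direction (ties round cranially); the center is
    the in-plane centroid of the lumen cross-section in that slice, rounded
    to the nearest voxel.  Returned in *full-volume* coordinates.
    """
    sz = spacing[2]
    offset = int(np.floor(10.0 * height_cm / sz + 0.5))  # half rounds toward cranial
    k = landmark.ridge_slice + cranial_direction * offset
    if not (0 <= k < CROP_SIZE):
        raise PlacementError(
            f"target slice {k} for height {height_cm} cm falls outside the 61^3 crop"
        )
    cross = mask.mask_full[:, :, k]
    if not cross.any():
        raise PlacementError(f"empty lumen cross-section at height {height_cm} cm (slice {k})")
    ci, cj = ndimage.center_of_mass(cross)
    return mask.to_full(VoxelIndex(int(round(ci)), int(round(cj)), int(k)))


def mask_labels(mask: AirwayMask) -> np.ndarray:
    """Label image for export: 1 = eroded truth region, 2 = eroded-away shell."""
    labels = np.zeros((CROP_SIZE,) * 3, dtype=np.uint8)
    labels[mask.mask_full & ~mask.mask_eroded] = 2
    labels[mask.mask_eroded] = 1
    return labels
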