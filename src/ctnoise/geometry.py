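"""CT volume container and the geometric voxel-selection primitives.

A :class:`CTVolume` stores Hounsfield-unit values on a regular grid with
anisotropic physical spacing.  Array axes are ``(i, j, k)`` where ``i, j``
are the in-plane (x, y) axes and ``k`` is the cranio-caudal (z) axis; an
axial slice is a fixed ``k``.  All distances are measured between voxel
centers in millimetres, with the per-axis spacing applied.

The region-of-interest primitives select voxels with the *center-in*
criterion: a voxel belongs to a circle or sphere iff its center lies within
the radius.  This matches how clinical ROI tools count pixels and keeps
voxel counts integer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, NamedTuple

import numpy as np

from .errors import BoundaryError, InvalidParameterError

__all__ = [
    "CTVolume",
    "VoxelIndex",
    "MeasurementShape",
    "radius_from_area",
    "sphere_volume_cm3",
    "select_circle",
    "select_sphere",
    "circle_offsets",
    "sphere_offsets",
]


class VoxelIndex(NamedTuple):
    """0-based integer grid coordinates (i, j in-plane; k axial)."""

    i: int
    j: int
    k: int


@dataclass(frozen=True)
class CTVolume:
    """A 3-D grid of HU values with physical voxel spacing in mm.

    Parameters
    ----------
    values
        3-D float array of CT numbers (HU), axis order ``(i, j, k)``.
    spacing
        Per-axis voxel size in mm: ``(x, y, z)`` where z is the slice
        increment along the cranio-caudal axis.
    axis_order
        Convention tag; always ``"xyz"`` for arrays produced by this
        package (axis 0 = x, axis 1 = y, axis 2 = z/axial).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    axis_order: str = "xyz"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        spacing = tuple(float(s) for s in self.spacing)
        object.__setattr__(self, "spacing", spacing)
        if values.ndim != 3 or min(values.shape) < 1:
            raise InvalidParameterError(
                f"CT volume must be a 3-D grid with >= 1 voxel per axis, got shape {values.shape}"
            )
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise InvalidParameterError(f"voxel spacing must be positive per axis, got {spacing}")
        if not np.all(np.isfinite(values)):
            raise InvalidParameterError("HU values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def contains(self, index: VoxelIndex) -> bool:
        return all(0 <= c < n for c, n in zip(index, self.shape))


@dataclass(frozen=True)
class MeasurementShape:
    """A circular ROI (one axial slice) or spherical VOI (may span slices)."""

    kind: Literal["circle", "sphere"]
    center: VoxelIndex
    radius_mm: float

    def __post_init__(self) -> None:
        if self.kind not in ("circle", "sphere"):
            raise InvalidParameterError(f"shape kind must be 'circle' or 'sphere', got {self.kind!r}")
        if self.radius_mm <= 0:
            raise InvalidParameterError(f"radius must be positive, got {self.radius_mm}")
        object.__setattr__(self, "center", VoxelIndex(*self.center))


def radius_from_area(area_cm2: float) -> float:
    """Radius in mm of a circle with the given area in cm².

    The same radius defines both the circular ROI and the spherical VOI;
    the conventional 1.0 cm² ROI gives r = sqrt(100/pi) ≈ 5.6419 mm and a
    VOI of approximately 0.75 cm³.
    """
    if not (area_cm2 > 0):
        raise InvalidParameterError(f"area must be positive, got {area_cm2}")
    return math.sqrt(100.0 * area_cm2 / math.pi)


def sphere_volume_cm3(radius_mm: float) -> float:
    """Volume in cm³ of a sphere with the given radius in mm."""
    if radius_mm <= 0:
        raise InvalidParameterError(f"radius must be positive, got {radius_mm}")
    return (4.0 / 3.0) * math.pi * radius_mm**3 / 1000.0


def circle_offsets(spacing: tuple[float, float, float], radius_mm: float) -> np.ndarray:
    """Integer (di, dj, 0) offsets whose in-plane center distance is <= radius.

    Offsets are returned sorted lexicographically and depend only on the
    in-plane spacing, so they can be reused for every center.
    """
    sx, sy, _ = spacing
    ni = int(math.floor(radius_mm / sx))
    nj = int(math.floor(radius_mm / sy))
    di, dj = np.meshgrid(np.arange(-ni, ni + 1), np.arange(-nj, nj + 1), indexing="ij")
    keep = (di * sx) ** 2 + (dj * sy) ** 2 <= radius_mm**2
    offs = np.stack([di[keep], dj[keep], np.zeros(int(keep.sum()), dtype=np.int64)], axis=1)
    order = np.lexsort((offs[:, 2], offs[:, 1], offs[:, 0]))
    return offs[order]


def sphere_offsets(spacing: tuple[float, float, float], radius_mm: float) -> np.ndarray:
    """Integer (di, dj, dk) offsets whose anisotropic center distance is <= radius."""
    sx, sy, sz = spacing
    ni = int(math.floor(radius_mm / sx))
    nj = int(math.floor(radius_mm / sy))
    nk = int(math.floor(radius_mm / sz))
    di, dj, dk = np.meshgrid(
        np.arange(-ni, ni + 1),
        np.arange(-nj, nj + 1),
        np.arange(-nk, nk + 1),
        indexing="ij",
    )
    keep = (di * sx) ** 2 + (dj * sy) ** 2 + (dk * sz) ** 2 <= radius_mm**2
    offs = np.stack([di[keep], dj[keep], dk[keep]], axis=1)
    order = np.lexsort((offs[:, 2], offs[:, 1], offs[:, 0]))
    return offs[order]


def _check_bounds(volume: CTVolume, center: VoxelIndex, offsets: np.ndarray, what: str) -> np.ndarray:
    center = VoxelIndex(*center)
    if not volume.contains(center):
        raise BoundaryError(f"center {tuple(center)} outside grid {volume.shape}")
    voxels = np.asarray(center, dtype=np.int64) + offsets
    if np.any(voxels < 0) or np.any(voxels >= np.asarray(volume.shape)):
        raise BoundaryError(
            f"{what} of radius extends past the grid boundary at center {tuple(center)}"
        )
    return voxels


def select_circle(volume: CTVolume, center: VoxelIndex, radius_mm: float) -> np.ndarray:
    """Voxel indices of the circular ROI in the center's axial slice.

    Returns an (n, 3) integer array of (i, j, k) indices; raises
    :class:`BoundaryError` if the circle extends past the grid.
    """
    if radius_mm <= 0:
        raise InvalidParameterError(f"radius must be positive, got {radius_mm}")
    return _check_bounds(volume, center, circle_offsets(volume.spacing, radius_mm), "circle")


def select_sphere(volume: CTVolume, center: VoxelIndex, radius_mm: float) -> np.ndarray:
    """Voxel indices of the spherical VOI around the center.

    Anisotropic spacing is applied per axis, so the voxel count depends on
    the in-plane field of view and on the slice increment.
    """
    if radius_mm <= 0:
        raise InvalidParameterError(f"radius must be positive, got {radius_mm}")
    return _check_bounds(volume, center, sphere_offsets(volume.spacing, radius_mm), "sphere")
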