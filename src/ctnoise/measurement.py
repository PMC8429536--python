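"""Simulated repeated manual noise measurement.

A human reader never hits the exact lumen centroid twice, so repeated
manual placement is emulated deterministically: the computed isocenter is
displaced by one voxel in every combination of x, y and z, giving 27
candidate positions.  At each position the noise (sample SD of HU) is
measured with both the circular ROI and the spherical VOI of equal radius.

Containment exclusion: if *either* shape contains any voxel outside the
pre-erosion lumen segmentation, *both* shapes are excluded at that
position — a reader would reject a placement visibly touching the wall
regardless of the tool.  Excluded positions are retained in the output so
the exclusion accounting is exact.

Per scan, the measurement height above the carina (1.0, 1.5 or 2.0 cm) with
the fewest exclusions is kept, accounting for anatomical variation; ties go
to the lowest height, closest to the carina and most reliably intraluminal.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Literal, Sequence

import numpy as np

from .errors import BoundaryError, PlacementError, ScanFailureError
from .geometry import CTVolume, VoxelIndex, radius_from_area, select_circle, select_sphere
from .segmentation import AirwayMask, CarinaLandmark, measurement_center, true_noise

__all__ = [
    "NoiseMeasurement",
    "ScanMeasurementSet",
    "MEASUREMENT_HEIGHTS_CM",
    "jitter_centroids",
    "measure_at",
    "evaluate_scan",
]

MEASUREMENT_HEIGHTS_CM: tuple[float, ...] = (1.0, 1.5, 2.0)
N_JITTER = 27


@dataclass(frozen=True)
class NoiseMeasurement:
    """One SD estimate (or exclusion) for one shape at one jitter position."""

    shape_kind: Literal["circle", "sphere"]
    center: VoxelIndex
    height_cm: float
    n_voxels: int
    excluded: bool
    noise_hu: float | None

    def __post_init__(self) -> None:
        if self.excluded and self.noise_hu is not None:
            raise ValueError("excluded measurements carry no noise value")
        if not self.excluded and self.noise_hu is None:
            raise ValueError("kept measurements must carry a noise value")
        object.__setattr__(self, "center", VoxelIndex(*self.center))


@dataclass(frozen=True)
class ScanMeasurementSet:
    """All 27 paired (circle, sphere) measurements for one scan."""

    scan_id: str
    height_cm: float
    pairs: tuple[tuple[NoiseMeasurement, NoiseMeasurement], ...]
    true_noise_hu: float

    def __post_init__(self) -> None:
        if len(self.pairs) != N_JITTER:
            raise ValueError(f"a scan carries exactly {N_JITTER} jitter positions, got {len(self.pairs)}")
        for circle, sphere in self.pairs:
            if circle.excluded != sphere.excluded:
                raise ValueError("circle and sphere at one position must share exclusion status")

    @property
    def n_excluded(self) -> int:
        return sum(c.excluded for c, _ in self.pairs)

    @property
    def n_kept(self) -> int:
        return N_JITTER - self.n_excluded

    def kept_pairs(self) -> list[tuple[NoiseMeasurement, NoiseMeasurement]]:
        return [(c, s) for c, s in self.pairs if not c.excluded]


def jitter_centroids(center: VoxelIndex) -> list[VoxelIndex]:
    """The 27 one-voxel jitter positions around (and including) a center.

    Deterministic lexicographic order over offsets (di, dj, dk) in
    {−1, 0, 1}³; the unjittered center appears exactly once.  The jitter is
    one *voxel* per axis, so with anisotropic spacing the displacements are
    anisotropic in millimetres, as on a real scanner console.
    """
    center = VoxelIndex(*center)
    if min(center) < 1:
        raise BoundaryError(f"center {tuple(center)} too close to the grid edge for a one-voxel jitter")
    return [
        VoxelIndex(center.i + di, center.j + dj, center.k + dk)
        for di, dj, dk in product((-1, 0, 1), repeat=3)
    ]


def measure_at(
    volume: CTVolume,
    mask: AirwayMask,
    center: VoxelIndex,
    radius_mm: float,
    height_cm: float = float("nan"),
) -> tuple[NoiseMeasurement, NoiseMeasurement]:
    """Measure ROI and VOI noise at one position, applying the exclusion rule.

    Returns the (circle, sphere) pair; both are excluded if either shape
    contains a voxel outside the pre-erosion segmentation.
    """
    circle_vox = select_circle(volume, center, radius_mm)
    sphere_vox = select_sphere(volume, center, radius_mm)
    contained = mask.contains_full(circle_vox).all() and mask.contains_full(sphere_vox).all()

    def build(kind: Literal["circle", "sphere"], vox: np.ndarray) -> NoiseMeasurement:
        noise = (
            float(np.std(volume.values[vox[:, 0], vox[:, 1], vox[:, 2]], ddof=1))
            if contained
            else None
        )
        return NoiseMeasurement(
            shape_kind=kind,
            center=center,
            height_cm=height_cm,
            n_voxels=len(vox),
            excluded=not contained,
            noise_hu=noise,
        )

    return build("circle", circle_vox), build("sphere", sphere_vox)


def evaluate_scan(
    volume: CTVolume,
    mask: AirwayMask,
    landmark: CarinaLandmark,
    area_cm2: float = 1.0,
    heights_cm: Sequence[float] = MEASUREMENT_HEIGHTS_CM,
    scan_id: str = "scan",
    cranial_direction: int = +1,
) -> ScanMeasurementSet:
    """Run the full per-scan measurement: heights, jitter, exclusion, selection.

    For each candidate height the lumen centroid is computed, jittered to 27
    positions and measured; the height with the fewest exclusions is kept
    (tie-break: lowest height).  Raises :class:`ScanFailureError` when no
    height can be placed.
    """
    radius = radius_from_area(area_cm2)
    truth = true_noise(volume, mask)
    best: ScanMeasurementSet | None = None
    for height in heights_cm:
        try:
            center = measurement_center(mask, landmark, height, volume.spacing, cranial_direction)
            pairs = tuple(
                measure_at(volume, mask, pos, radius, height_cm=height)
                for pos in jitter_centroids(center)
            )
        except (PlacementError, BoundaryError):
            continue
        candidate = ScanMeasurementSet(
            scan_id=scan_id,
            height_cm=height,
            pairs=pairs,
            true_noise_hu=truth,
        )
        if best is None or candidate.n_excluded < best.n_excluded:
            best = candidate
    if best is None:
        raise ScanFailureError(f"{scan_id}: no measurement height could be placed")
    return best
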