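"""End-to-end study orchestration: cohort in, comparison report out.

For every scan the pipeline runs segmentation → carina landmark → jittered
ROI/VOI measurement, then pools the kept measurements of all scans into one
Bland-Altman analysis per shape, the Levene variability test and the
Wilcoxon bias test, together with the exclusion accounting
(27 jitter positions per scan; discarded + kept = total).

Two dose arms (regular vs ultra-low dose) are treated as two independent
cohorts: run this once per arm.  Scans whose segmentation or placement
fails are skipped with a logged reason and reported, never fatal.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import CTNoiseError, UndefinedStatisticError
from .geometry import CTVolume, VoxelIndex
from .measurement import N_JITTER, ScanMeasurementSet, evaluate_scan
from .phantom import Phantom
from .segmentation import detect_carina, segment_airway
from .stats import MethodComparison, compare_methods, wilcoxon_bias_test

__all__ = ["ScanInput", "StudyReport", "run_study", "measurements_frame"]


def measurements_frame(scans: Sequence[ScanMeasurementSet]) -> pd.DataFrame:
    """Long-format table: one row per shape per jitter position per scan."""
    rows = []
    for scan in scans:
        for pos, pair in enumerate(scan.pairs):
            for m in pair:
                rows.append(
                    {
                        "scan_id": scan.scan_id,
                        "height_cm": scan.height_cm,
                        "jitter_position": pos,
                        "center_i": m.center.i,
                        "center_j": m.center.j,
                        "center_k": m.center.k,
                        "shape": m.shape_kind,
                        "n_voxels": m.n_voxels,
                        "noise_hu": m.noise_hu,
                        "excluded": m.excluded,
                        "true_noise_hu": scan.true_noise_hu,
                    }
                )
    return pd.DataFrame(rows)

logger = logging.getLogger("ctnoise")


@dataclass(frozen=True)
class ScanInput:
    """One cohort entry: a calibrated HU volume plus an air seed point."""

    scan_id: str
    volume: CTVolume
    seed_point: VoxelIndex
    cranial_direction: int = +1


@dataclass
class StudyReport:
    """Pooled study results with full per-measurement bookkeeping."""

    scans: list[ScanMeasurementSet]
    failures: list[tuple[str, str]]
    comparison: MethodComparison
    wilcoxon_unit: str
    total_positions: int
    discarded_positions: int

    @property
    def n_scans(self) -> int:
        return len(self.scans)

    @property
    def kept_positions(self) -> int:
        return self.total_positions - self.discarded_positions

    @property
    def exclusion_rate_pct(self) -> float:
        return 100.0 * self.discarded_positions / self.total_positions

    @property
    def variability_reduction_pct(self) -> float:
        return self.comparison.variability_reduction_pct

    def measurements(self) -> pd.DataFrame:
        """Long-format measurement table for all scans in the study."""
        return measurements_frame(self.scans)

    def to_dict(self) -> dict:
        c = self.comparison
        return {
            "n_scans": self.n_scans,
            "failed_scans": [{"scan_id": s, "reason": r} for s, r in self.failures],
            "total_positions": self.total_positions,
            "discarded_positions": self.discarded_positions,
            "exclusion_rate_pct": self.exclusion_rate_pct,
            "circle": {
                "bias_hu": c.circle.bias,
                "loa_low_hu": c.circle.loa_low,
                "loa_high_hu": c.circle.loa_high,
                "loa_distance_hu": c.circle.loa_distance,
                "n": c.circle.n,
            },
            "sphere": {
                "bias_hu": c.sphere.bias,
                "loa_low_hu": c.sphere.loa_low,
                "loa_high_hu": c.sphere.loa_high,
                "loa_distance_hu": c.sphere.loa_distance,
                "n": c.sphere.n,
            },
            "variability_reduction_pct": self.variability_reduction_pct,
            "levene": {"statistic": c.levene_statistic, "p": c.levene_p},
            "wilcoxon": {
                "statistic": c.wilcoxon_statistic,
                "p": c.wilcoxon_p,
                "unit": self.wilcoxon_unit,
            },
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)


def _as_scan_input(item: Phantom | ScanInput, index: int) -> ScanInput:
    if isinstance(item, ScanInput):
        return item
    if isinstance(item, Phantom):
        return ScanInput(
            scan_id=f"phantom-{index:03d}",
            volume=item.volume,
            seed_point=item.suggested_seed_point(),
        )
    raise TypeError(f"cohort entries must be Phantom or ScanInput, got {type(item)!r}")


def run_study(
    cohort: Sequence[Phantom | ScanInput],
    area_cm2: float = 1.0,
    hu_threshold: float = -500.0,
    wilcoxon_unit: Literal["position", "scan"] = "position",
) -> StudyReport:
    """Run the full ROI-vs-VOI precision study on a cohort.

    ``wilcoxon_unit`` selects the pairing for the signed-rank bias test:
    per kept measurement position (default) or per scan (mean difference
    per scan, one pair per scan).  Fully deterministic given the cohort.
    """
    scans: list[ScanMeasurementSet] = []
    failures: list[tuple[str, str]] = []
    for index, item in enumerate(cohort):
        scan = _as_scan_input(item, index)
        try:
            mask = segment_airway(scan.volume, scan.seed_point, hu_threshold)
            landmark = detect_carina(mask, cranial_direction=scan.cranial_direction)
            result = evaluate_scan(
                scan.volume,
                mask,
                landmark,
                area_cm2=area_cm2,
                scan_id=scan.scan_id,
                cranial_direction=scan.cranial_direction,
            )
        except CTNoiseError as exc:
            logger.warning("scan %s skipped: %s", scan.scan_id, exc)
            failures.append((scan.scan_id, str(exc)))
            continue
        for pos, (circle, _) in enumerate(result.pairs):
            if circle.excluded:
                logger.info(
                    "scan %s height %.1f cm jitter %d excluded: shape crosses the segmentation boundary",
                    scan.scan_id, result.height_cm, pos,
                )
        scans.append(result)
    if len(scans) < 2:
        raise UndefinedStatisticError(f"study needs >= 2 measurable scans, got {len(scans)}")

    circle_vals, sphere_vals, truths, scan_ids = [], [], [], []
    for s in scans:
        for circle, sphere in s.kept_pairs():
            circle_vals.append(circle.noise_hu)
            sphere_vals.append(sphere.noise_hu)
            truths.append(s.true_noise_hu)
            scan_ids.append(s.scan_id)
    comparison = compare_methods(circle_vals, sphere_vals, truths)
    if wilcoxon_unit == "scan":
        d = pd.DataFrame(
            {
                "scan": scan_ids,
                "dc": np.asarray(circle_vals) - np.asarray(truths),
                "ds": np.asarray(sphere_vals) - np.asarray(truths),
            }
        ).groupby("scan").mean()
        stat, p = wilcoxon_bias_test(d["dc"].to_numpy(), d["ds"].to_numpy())
        comparison = MethodComparison(
            circle=comparison.circle,
            sphere=comparison.sphere,
            levene_statistic=comparison.levene_statistic,
            levene_p=comparison.levene_p,
            wilcoxon_statistic=stat,
            wilcoxon_p=p,
        )
    total = N_JITTER * len(scans)
    discarded = sum(s.n_excluded for s in scans)
    return StudyReport(
        scans=scans,
        failures=failures,
        comparison=comparison,
        wilcoxon_unit=wilcoxon_unit,
        total_positions=total,
        discarded_positions=discarded,
    )
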