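"""Agreement and comparison statistics for ROI vs VOI noise estimates.

Bland-Altman analysis quantifies how a measurement method agrees with the
ground truth: the *bias* is the mean difference (measured − truth) and the
limits of agreement (LoA) are bias ± 1.96 · SD of the differences.  The
distance between the limits, 2 · 1.96 · SD, is the operational definition
of measurement variability here.  All 27 jitter measurements of a scan are
pooled against that scan's single ground-truth value, so the plots show
vertical stripes per scan; the LoA carry no repeated-measures correction
(a caveat documented in the methods note).

Method comparison uses two paired tests: Levene's test (classic,
mean-centered) on the difference distributions, because the LoA distance is
a direct function of their variances, and the Wilcoxon signed-rank test on
the paired differences for a shift in bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import UndefinedStatisticError

__all__ = [
    "AgreementResult",
    "MethodComparison",
    "LOA_MULTIPLIER",
    "bland_altman",
    "levene_variability_test",
    "wilcoxon_bias_test",
    "compare_methods",
]

LOA_MULTIPLIER = 1.96  # conventional Bland-Altman constant


@dataclass(frozen=True)
class AgreementResult:
    """Bland-Altman summary of one method against ground truth (HU)."""

    bias: float
    loa_low: float
    loa_high: float
    loa_distance: float
    n: int

    def __post_init__(self) -> None:
        if not (self.loa_low <= self.bias <= self.loa_high):
            raise ValueError("bias must lie within the limits of agreement")


@dataclass(frozen=True)
class MethodComparison:
    """Agreement of both methods plus the two hypothesis tests."""

    circle: AgreementResult
    sphere: AgreementResult
    levene_statistic: float
    levene_p: float
    wilcoxon_statistic: float
    wilcoxon_p: float

    @property
    def variability_reduction_pct(self) -> float:
        """100 · (1 − LoA-distance ratio sphere/circle); positive = VOI tighter."""
        return 100.0 * (1.0 - self.sphere.loa_distance / self.circle.loa_distance)


def bland_altman(measured: Sequence[float], truth: Sequence[float]) -> AgreementResult:
    """Bland-Altman agreement of measured values against ground truth.

    ``truth`` may repeat one value per scan across its jitter measurements.
    Differences are measured − truth; the LoA use the sample SD.
    """
    m = np.asarray(measured, dtype=float)
    t = np.asarray(truth, dtype=float)
    if m.shape != t.shape:
        raise UndefinedStatisticError(f"length mismatch: {m.shape} vs {t.shape}")
    if m.size < 2:
        raise UndefinedStatisticError("Bland-Altman needs at least 2 paired values")
    d = m - t
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    half = LOA_MULTIPLIER * sd
    return AgreementResult(
        bias=bias,
        loa_low=bias - half,
        loa_high=bias + half,
        loa_distance=2.0 * half,
        n=int(m.size),
    )


def levene_variability_test(diffs_a: Sequence[float], diffs_b: Sequence[float]) -> tuple[float, float]:
    """Levene's test for equal variance of two difference distributions.

    Classic mean-centered variant: a one-way ANOVA F test on the absolute
    deviations from each group's mean.  Two constant groups have no
    variance difference by convention (statistic 0, p = 1).
    """
    a = np.asarray(diffs_a, dtype=float)
    b = np.asarray(diffs_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise UndefinedStatisticError("Levene's test needs >= 2 values per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 0.0, 1.0
    stat, p = sps.levene(a, b, center="mean")
    return float(stat), float(p)


def wilcoxon_bias_test(
    diffs_a: Sequence[float],
    diffs_b: Sequence[float],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired differences (a − b).

    Pairs are per measurement position; zero paired-differences are dropped
    per the Wilcoxon convention.  The p-value is exact for n ≤ 25 without
    ties, otherwise a normal approximation with tie correction is used.
    """
    a = np.asarray(diffs_a, dtype=float)
    b = np.asarray(diffs_b, dtype=float)
    if a.shape != b.shape:
        raise UndefinedStatisticError(f"paired inputs must have equal length: {a.shape} vs {b.shape}")
    d = a - b
    nonzero = d[d != 0]
    if nonzero.size < 1:
        raise UndefinedStatisticError("no nonzero paired differences; signed-rank test undefined")
    has_ties = np.unique(np.abs(nonzero)).size < nonzero.size
    method = "exact" if (nonzero.size <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(
        a, b, zero_method="wilcox", alternative=alternative, method=method, correction=False
    )
    return float(res.statistic), float(res.pvalue)


def compare_methods(
    circle_measured: Sequence[float],
    sphere_measured: Sequence[float],
    truth: Sequence[float],
) -> MethodComparison:
    """Full ROI-vs-VOI comparison on position-aligned kept measurements."""
    circle = bland_altman(circle_measured, truth)
    sphere = bland_altman(sphere_measured, truth)
    d_circle = np.asarray(circle_measured, dtype=float) - np.asarray(truth, dtype=float)
    d_sphere = np.asarray(sphere_measured, dtype=float) - np.asarray(truth, dtype=float)
    lev_stat, lev_p = levene_variability_test(d_circle, d_sphere)
    wil_stat, wil_p = wilcoxon_bias_test(d_circle, d_sphere)
    return MethodComparison(
        circle=circle,
        sphere=sphere,
        levene_statistic=lev_stat,
        levene_p=lev_p,
        wilcoxon_statistic=wil_stat,
        wilcoxon_p=wil_p,
    )
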