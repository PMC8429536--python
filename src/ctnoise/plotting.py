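"""Bland-Altman residual plots for study reports.

Each panel plots the per-measurement difference (measured − truth, HU)
against the scan's ground-truth noise, with horizontal lines at the bias
and the limits of agreement.  Because every scan has a single truth value
shared by its 27 jitter measurements, the points form vertical stripes.
"""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .stats import AgreementResult
from .study import StudyReport

__all__ = ["bland_altman_axes", "plot_report", "plot_arms"]


def bland_altman_axes(ax: plt.Axes, truths: Sequence[float], diffs: Sequence[float], agreement: AgreementResult, title: str) -> None:
    """Draw one Bland-Altman residual panel onto an existing axes."""
    ax.scatter(truths, diffs, s=8, alpha=0.5, color="tab:blue", edgecolors="none")
    ax.axhline(agreement.bias, color="k", lw=1.2, label=f"bias {agreement.bias:+.1f} HU")
    for loa in (agreement.loa_low, agreement.loa_high):
        ax.axhline(loa, color="k", lw=0.8, ls="--")
    ax.set_title(title, fontsize=10)
    ax.set_xlabel("ground-truth noise (HU)")
    ax.set_ylabel("measured − truth (HU)")
    ax.legend(fontsize=8, loc="upper right")


def _panel(ax: plt.Axes, report: StudyReport, shape: str, title: str) -> None:
    df = report.measurements()
    kept = df[(df["shape"] == shape) & (~df["excluded"])]
    diffs = kept["noise_hu"] - kept["true_noise_hu"]
    agreement = report.comparison.circle if shape == "circle" else report.comparison.sphere
    bland_altman_axes(ax, kept["true_noise_hu"], diffs, agreement, title)


def plot_report(report: StudyReport, path: str | None = None) -> plt.Figure:
    """Two-panel (ROI, VOI) Bland-Altman figure for one study arm."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    _panel(axes[0], report, "circle", "circular ROI")
    _panel(axes[1], report, "sphere", "spherical VOI")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
    return fig


def plot_arms(reports: dict[str, StudyReport], path: str | None = None) -> plt.Figure:
    """Four-panel figure: ROI and VOI for each of two dose arms/noise regimes."""
    fig, axes = plt.subplots(len(reports), 2, figsize=(9, 4 * len(reports)), squeeze=False, sharey="row")
    for row, (label, report) in enumerate(reports.items()):
        _panel(axes[row][0], report, "circle", f"{label}: circular ROI")
        _panel(axes[row][1], report, "sphere", f"{label}: spherical VOI")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
    return fig
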