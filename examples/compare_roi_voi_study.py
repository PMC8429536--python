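"""Run the cohort-level ROI-vs-VOI precision study on synthetic scans.

Generates a cohort with per-scan true noise drawn from 26-39 HU (an
ultra-low-dose-like regime), runs the full pipeline on every scan, and
compares the two methods with Bland-Altman agreement, Levene's variance
test and the Wilcoxon signed-rank bias test.
"""

from ctnoise import generate_cohort, run_study

cohort = generate_cohort(n_scans=12, sigma_range=(26.0, 39.0), seed=5)
report = run_study(cohort)
summary = report.to_dict()

print(f"scans analysed: {report.n_scans}")
print(f"positions: {report.total_positions} total, {report.discarded_positions} excluded "
      f"({report.exclusion_rate_pct:.1f}%)")
print(f"ROI  bias {summary['circle']['bias_hu']:+.2f} HU, "
      f"LoA distance {summary['circle']['loa_distance_hu']:.2f} HU")
print(f"VOI  bias {summary['sphere']['bias_hu']:+.2f} HU, "
      f"LoA distance {summary['sphere']['loa_distance_hu']:.2f} HU")
print(f"variability reduction: {report.variability_reduction_pct:.0f}%")
print(f"Levene p = {summary['levene']['p']:.2e}, Wilcoxon p = {summary['wilcoxon']['p']:.3f}")
# A large reduction with a tiny Levene p means the spherical VOI agrees
# with the ground truth far more tightly; a small bias shift means the
# volumetric approach does not trade accuracy for that precision.
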