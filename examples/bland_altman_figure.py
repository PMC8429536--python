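"""Produce the Bland-Altman residual figure for two noise regimes.

Each panel plots measured-minus-truth differences against the scan's
ground-truth noise, with the bias and the limits of agreement as
horizontal lines; the 27 jitter measurements of each scan share one truth
value, so points stack in vertical stripes.
"""

from ctnoise import generate_cohort, run_study
from ctnoise.plotting import plot_arms

reports = {}
for label, sigma_range, seed in [
    ("regular dose", (17.0, 29.0), 11),
    ("ultra-low dose", (26.0, 39.0), 12),
]:
    cohort = generate_cohort(n_scans=10, sigma_range=sigma_range, seed=seed)
    reports[label] = run_study(cohort)

plot_arms(reports, path="bland_altman.png")
print("wrote bland_altman.png (rows: dose regimes; columns: ROI vs VOI)")
for label, report in reports.items():
    print(f"{label}: LoA distance ROI {report.comparison.circle.loa_distance:.2f} HU "
          f"vs VOI {report.comparison.sphere.loa_distance:.2f} HU")
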