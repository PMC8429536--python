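# ctnoise

Volume-based CT image-noise estimation in the tracheal air column.

## The problem

Image noise in computed tomography is routinely quantified as the standard
deviation (SD) of Hounsfield-unit (HU) values inside a physically
homogeneous region — in chest CT, a 1-cm² circular region of interest (ROI)
placed in the trachea. That single-slice estimate is imprecise: its
sampling error scales as σ/√(2n) with the voxel count n, and a manually
placed ROI rarely lands on the same voxels twice. Replacing the circle with
a sphere of the same radius (a volume of interest, VOI, ≈ 0.75 cm³) raises
n by roughly an order of magnitude at no extra reading effort, and should
tighten repeated measurements accordingly.

`ctnoise` implements and validates that comparison for radiologists,
medical physicists and image-analysis researchers who need reliable noise
estimates for protocol optimisation or densitometry QA:

- **geometry** — circle/sphere voxel selection with anisotropic spacing and
  the area→radius convention r = √(A/π) (1.0 cm² → 5.6419 mm);
- **segmentation** — 26-connected region growing of tracheal air in a 61³
  crop around a seed, one-voxel morphological erosion against
  partial-volume edge effects, and the eroded-lumen SD as the per-scan
  ground-truth noise;
- **measurement** — deterministic one-voxel jitter of the lumen centroid
  (27 positions) to simulate repeated manual placement, paired ROI/VOI
  noise at each position, a containment exclusion rule (if either shape
  leaves the pre-erosion segmentation, both are discarded), and per-scan
  selection of the measurement height above the carina ridge (1.0, 1.5 or
  2.0 cm) with the fewest rejections;
- **stats** — Bland-Altman agreement against the ground truth (bias,
  limits of agreement, LoA distance = 2·1.96·SD of the differences),
  Levene's test on the difference variances and the Wilcoxon signed-rank
  test on paired biases;
- **phantom** — synthetic bifurcating-airway chest phantoms with known
  injected Gaussian noise (optionally spatially correlated), standing in
  for patient cohorts;
- **study** — cohort orchestration with exclusion accounting and JSON/CSV
  reports, plus a thin `ctnoise` CLI (`phantom generate`, `segment`,
  `measure`, `study run`, `report plot`).

## Worked example

```python
from ctnoise import generate_cohort, run_study

cohort = generate_cohort(n_scans=12, sigma_range=(26.0, 39.0), seed=5)
report = run_study(cohort)
print(report.to_json())
```

Running `python examples/compare_roi_voi_study.py` (which does exactly
this) prints:

```
scans analysed: 12
positions: 324 total, 0 excluded (0.0%)
ROI  bias -0.21 HU, LoA distance 5.51 HU
VOI  bias -0.13 HU, LoA distance 1.28 HU
variability reduction: 77%
Levene p = 1.04e-58, Wilcoxon p = 0.090
```

Both methods are essentially unbiased (bias a fraction of an HU), but the
spherical VOI's limits of agreement are several times tighter than the
circular ROI's: repeated "manual" placements of the VOI disagree far less
with the true noise. The Levene p-value confirms the variance difference;
the Wilcoxon p tests for a bias shift between the methods. On these
iid-noise phantoms the reduction approaches the √(n_ROI/n_VOI) limit
(≈ 69% at 0.7 mm voxels); clinical reconstruction noise is spatially
correlated, which lowers the attainable gain.

Further examples in `examples/`: phantom generation, a single-scan
measurement walk-through, and the Bland-Altman panel figure.

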