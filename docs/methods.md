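# Methods

## Noise model and estimand

CT image noise is defined operationally as the standard deviation of HU
values over a physically homogeneous region of intra-thoracic air. For a
region of n voxels with iid noise of true SD σ, the sample SD is unbiased
to first order with sampling error ≈ σ/√(2n); every precision claim in
this package reduces to that scaling. The sample (n−1) denominator is used
everywhere — the estimand is a population SD estimated from a sample; the
difference from the population denominator is < 0.5% for n ≥ 100.

The per-scan ground truth is the SD over the segmented tracheal air after
a one-voxel erosion. Erosion removes the boundary shell where
partial-volume blending with the airway wall inflates the SD; on phantoms
with sharp walls the eroded and uneroded values coincide, on real scans
they do not.

## Geometry

The ROI is a circle of area A (default 1.0 cm²) in one axial slice; the
VOI is the sphere with the same radius r = √(100·A/π) mm (5.6419 mm,
volume 0.752 cm³). Voxel membership uses the center-in criterion — a voxel
belongs iff its center lies within r of the center voxel's center,
distances taken in physical mm with per-axis spacing — matching how
clinical ROI tools count pixels and keeping counts integer. Published
voxel-count ranges for this protocol family (101–261 per ROI, 1117–2789
per VOI across patient-specific fields of view) are treated as consistency
envelopes, not exact targets, since the original membership rule is not
public. A shape that extends past the image grid is an error; only
crossing the *segmentation* boundary is an exclusion.

## Segmentation and landmark

Air is grown 26-connected from a user seed among voxels below −500 HU
inside a 61³ crop centered on the seed (clamped at image borders, then
zero-padded back to 61³ so the crop size is invariant). The threshold is
configurable; −500 HU sits ≈ 9σ from both air (−1000 HU) and tissue at the
noise levels of interest, so the noisy classification is effectively
deterministic. Erosion uses the full 3×3×3 cube — the minimal one-voxel
shell removal — in voxel units, because the exclusion bookkeeping is
voxel-based. A region touching all six crop faces raises a leak warning.

The carina ridge is defined combinatorially: the most caudal axial slice
whose lumen cross-section is a single 8-connected component while the next
caudal slice has two or more. This is deterministic, translation-invariant
and matches the anatomical ridge; volumes stored feet-up are handled by a
cranial-direction flag. The measurement isocenter at height h cm above the
ridge lies round(10·h/z-spacing) slices cranially (ties round cranially),
at the in-plane lumen centroid of that slice rounded to the nearest voxel.

## Jitter, exclusion, height selection

Repeated manual placement is simulated exhaustively, not randomly: all 27
offsets (±1 voxel per axis, lexicographic order, center included) are
evaluated, so this stage has no RNG. The jitter is one voxel per axis
literally; with anisotropic spacing the displacements are anisotropic in
mm, as on a scanner console. If either shape at a position contains any
voxel outside the pre-erosion segmentation, both shapes are excluded there
— a reader rejects a placement that visibly touches the wall regardless of
tool — and excluded positions are retained in the output so exclusion
rates are exactly reproducible. Of the candidate heights {1.0, 1.5, 2.0}
cm the one with the fewest exclusions is kept per scan; ties go to the
lowest height, which is closest to the carina and most reliably
intraluminal (the original tie rule is unstated; this one is declared).

## Statistics

Bland-Altman agreement pools all kept jitter measurements of all scans
against the per-scan truth: bias = mean(measured − truth), limits of
agreement bias ± 1.96·SD of differences, variability = LoA distance =
2·1.96·SD. The 1.96 multiplier is the conventional constant; no
repeated-measures correction is applied even though the 27 measurements
per scan are correlated — the pooled plot is replicated deliberately, and
LoA here compare methods rather than claim population coverage. Levene's
test uses classic mean-centering (not the Brown-Forsythe median variant);
two constant groups return (0, p = 1) by convention. The Wilcoxon
signed-rank test drops zero differences, is exact for ≤ 25 untied pairs
and otherwise uses the tie-corrected normal approximation; pairing is per
kept measurement position by default, with a per-scan aggregation (mean
difference per scan) available via `wilcoxon_unit="scan"` because the
natural pairing unit is debatable. Both tests are computed by scipy behind
this module's interface and are verified against independent hand-coded
references in the test suite.

## Phantom generator

The phantom emulates the measurement situation, not CT physics: a vertical
tracheal cylinder (default 18 mm lumen) splitting at a known slice into
two bronchi (12 mm, half-angle 30°, separated by a 1 mm carina septum so
the component-transition definition of the ridge holds exactly at the
requested slice), a 3 mm soft-tissue wall, parenchyma at −870 HU, on an
81³ grid at 0.7 mm isotropic spacing (the slice increment of a typical
1.0/0.7 mm thin-slice reconstruction; slice-thickness blurring is modeled
only through the optional noise smoothing). Exact tissue HU levels are
irrelevant to the SD pipeline as long as the air/tissue contrast dwarfs σ.
Additive Gaussian noise is injected with per-scan σ; cohorts draw σ
uniformly from a range (defaults 26–39 HU, an ultra-low-dose-like regime;
17–29 HU for a regular-dose arm) via a splittable seeded RNG, one
substream per scan. The noise field is normalized so the realized SD over
the reference lumen equals σ exactly — with the optional Gaussian
smoothing (which induces the spatial correlation of reconstructed CT
noise) a whole-field normalization would leave the lumen SD several
percent off.

What the phantom does *not* model: partial-volume blending at the wall,
streak/beam-hardening artifacts, non-Gaussian noise, anatomical
irregularity of the trachea, patient-specific fields of view. Passing
tests therefore demonstrate the correctness and the iid-limit behavior of
the measurement machinery, not clinical effect sizes: with iid noise the
VOI/ROI LoA ratio approaches √(n_ROI/n_VOI) ≈ 0.31 (a ≈ 69% variability
reduction at 0.7 mm voxels), whereas spatially correlated clinical noise
reduces the effective sample sizes and yields smaller observed gains
(40–53% in patient data at comparable voxel counts). The smoothing option
exists to explore that gap, not to reproduce it.

## Numerical and design choices

- Distances are voxel-center to voxel-center; boundary overflow of a shape
  is an error, never silently clipped.
- Spacing always comes from file headers; an absent or non-positive
  spacing is a hard read error (NIfTI headers are inspected raw, because
  common readers silently repair invalid pixdims to 1.0).
- Default study sizes: 49 scans per synthetic arm (matching a realistic
  single-center cohort) and, in the validation suite, 20 independently
  seeded cohorts for the precision-ordering property; one cohort takes a
  few seconds on a single core.
- Degenerate inputs fail loudly: SD of < 2 voxels, Wilcoxon with no
  nonzero pairs, Bland-Altman with < 2 pairs, all-tissue seeds, straight
  cylinders without a bifurcation.
- End-to-end determinism: identical inputs and seed give byte-identical
  reports; phantom geometry is cached and shared across a cohort, noise is
  per-scan.

## Known limitations

- The LoA carry no repeated-measures correction (see above); absolute LoA
  widths on real data should be interpreted comparatively.
- The containment rule uses the pre-erosion mask, so the exclusion rate of
  wide-lumen phantoms is 0%; realistic nonzero rates require narrow or
  irregular lumens, which the generator only produces via manual spec
  edits (narrowed-lumen behavior is exercised in the tests).
- Carina detection assumes the bifurcation is visible within the 61³ crop
  and that lumen cross-sections are simply connected at the ridge; severe
  noise or pathology could violate this on real scans.
- DICOM support expects a single consistent-orientation series with
  PixelSpacing present; no resampling or orientation normalization beyond
  the cranial-direction flag is performed.
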