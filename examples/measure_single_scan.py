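"""Measure ROI and VOI noise on one scan, end to end.

Pipeline: segment the tracheal air around a seed point, find the carina
ridge, place the measurement isocenter 1.0/1.5/2.0 cm above it, jitter it
by one voxel into 27 positions, and measure the SD of HU in a 1-cm^2
circular ROI and a ~0.75-cm^3 spherical VOI at each position.
"""

import numpy as np

from ctnoise import (
    PhantomSpec,
    detect_carina,
    evaluate_scan,
    generate_phantom,
    segment_airway,
)

phantom = generate_phantom(PhantomSpec(noise_sigma_hu=33.0, seed=1))
mask = segment_airway(phantom.volume, phantom.suggested_seed_point())
landmark = detect_carina(mask)
result = evaluate_scan(phantom.volume, mask, landmark, scan_id="demo")

circle_sds = [c.noise_hu for c, _ in result.kept_pairs()]
sphere_sds = [s.noise_hu for _, s in result.kept_pairs()]
print(f"chosen height: {result.height_cm} cm above the carina ridge")
print(f"kept positions: {result.n_kept}/27 (excluded: {result.n_excluded})")
print(f"ground-truth noise (eroded lumen SD): {result.true_noise_hu:.2f} HU")
print(f"ROI noise across jitter: {np.mean(circle_sds):.2f} +/- {np.std(circle_sds):.2f} HU")
print(f"VOI noise across jitter: {np.mean(sphere_sds):.2f} +/- {np.std(sphere_sds):.2f} HU")
# Both shapes are unbiased, but the VOI scatter across the 27 simulated
# re-placements is several times smaller: that is the precision gain.
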