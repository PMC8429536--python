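"""Airway segmentation, erosion, ground-truth noise and the carina landmark."""

import numpy as np
import pytest

from ctnoise import (
    AirwayMask,
    CarinaLandmark,
    CTVolume,
    NoBifurcationError,
    PlacementError,
    SeedPointError,
    SegmentationLeakWarning,
    VoxelIndex,
    detect_carina,
    measurement_center,
    segment_airway,
    true_noise,
)
from ctnoise.segmentation import CROP_SIZE, mask_labels


def brute_force_erosion(mask):
    """A voxel survives iff its full 3x3x3 neighborhood is inside the mask."""
    out = np.zeros_like(mask)
    n = mask.shape[0]
    for i in range(1, n - 1):
        for j in range(1, n - 1):
            for k in range(1, n - 1):
                out[i, j, k] = mask[i - 1 : i + 2, j - 1 : j + 2, k - 1 : k + 2].all()
    return out


class TestSegmentAirway:
    def test_noiseless_cylinder_mask_equals_geometry(self, make_cylinder):
        vol = make_cylinder(shape=(41, 41, 41), radius_mm=12.0)
        seed = VoxelIndex(20, 20, 20)
        mask = segment_airway(vol, seed)
        assert mask.crop_origin == (-10, -10, -10)
        # oracle: crop voxel is lumen iff its full-volume position is in the cylinder
        expected = np.zeros((CROP_SIZE,) * 3, dtype=bool)
        for ci in range(CROP_SIZE):
            for cj in range(CROP_SIZE):
                fi, fj = ci - 10, cj - 10
                if 0 <= fi < 41 and 0 <= fj < 41 and (fi - 20) ** 2 + (fj - 20) ** 2 <= 144:
                    expected[ci, cj, 10 : 10 + 41] = True
        np.testing.assert_array_equal(mask.mask_full, expected)

    def test_erosion_matches_brute_force_oracle(self, make_cylinder, noiseless_phantom):
        vol = make_cylinder(shape=(41, 41, 41), radius_mm=12.0)
        mask = segment_airway(vol, VoxelIndex(20, 20, 20))
        np.testing.assert_array_equal(mask.mask_eroded, brute_force_erosion(mask.mask_full))
        ph = noiseless_phantom
        mask2 = segment_airway(ph.volume, ph.suggested_seed_point())
        np.testing.assert_array_equal(mask2.mask_eroded, brute_force_erosion(mask2.mask_full))

    def test_seed_in_tissue_raises(self, make_cylinder):
        vol = make_cylinder()
        with pytest.raises(SeedPointError):
            segment_airway(vol, VoxelIndex(0, 0, 0), hu_threshold=-500.0)

    def test_all_air_volume_warns_about_leak(self):
        vol = CTVolume(values=np.full((70, 70, 70), -1000.0), spacing=(1.0, 1.0, 1.0))
        with pytest.warns(SegmentationLeakWarning):
            segment_airway(vol, VoxelIndex(35, 35, 35))

    def test_label_export_partitions_full_mask(self, noiseless_phantom):
        ph = noiseless_phantom
        mask = segment_airway(ph.volume, ph.suggested_seed_point())
        labels = mask_labels(mask)
        np.testing.assert_array_equal(labels == 1, mask.mask_eroded)
        np.testing.assert_array_equal(labels > 0, mask.mask_full)


class TestTrueNoise:
    def _mask_with(self, voxels):
        m = np.zeros((CROP_SIZE,) * 3, dtype=bool)
        for v in voxels:
            m[v] = True
        return AirwayMask(crop_origin=VoxelIndex(0, 0, 0), mask_full=m, mask_eroded=m)

    def test_constant_region_has_zero_noise(self):
        vol = CTVolume(values=np.full((CROP_SIZE,) * 3, -1000.0), spacing=(1.0, 1.0, 1.0))
        mask = self._mask_with([(5, 5, 5), (5, 5, 6), (5, 6, 5), (6, 5, 5)])
        assert true_noise(vol, mask) == 0.0

    def test_closed_form_sample_sd(self):
        values = np.full((CROP_SIZE,) * 3, -1000.0)
        values[5, 5, 5], values[5, 5, 6], values[5, 5, 7] = -1000.0, -998.0, -1002.0
        vol = CTVolume(values=values, spacing=(1.0, 1.0, 1.0))
        mask = self._mask_with([(5, 5, 5), (5, 5, 6), (5, 5, 7)])
        assert true_noise(vol, mask) == pytest.approx(2.0, abs=1e-12)

    def test_single_voxel_mask_is_undefined(self):
        from ctnoise import UndefinedStatisticError

        vol = CTVolume(values=np.zeros((CROP_SIZE,) * 3), spacing=(1.0, 1.0, 1.0))
        with pytest.raises(UndefinedStatisticError):
            true_noise(vol, self._mask_with([(5, 5, 5)]))

    def test_recovers_injected_sigma_within_2_percent(self, noisy_phantom):
        ph = noisy_phantom
        mask = segment_airway(ph.volume, ph.suggested_seed_point())
        assert mask.mask_eroded.sum() >= 10_000
        assert true_noise(ph.volume, mask) == pytest.approx(33.0, rel=0.02)

    def test_estimate_concentrates_at_sd_of_sd_rate(self):
        """|SD_hat - sigma| <= 4 sigma / sqrt(2n) with overwhelming frequency."""
        sigma = 25.0
        box = np.zeros((CROP_SIZE,) * 3, dtype=bool)
        box[10:22, 10:22, 10:22] = True  # n = 1728
        mask = AirwayMask(crop_origin=VoxelIndex(0, 0, 0), mask_full=box, mask_eroded=box)
        n = int(box.sum())
        bound = 4 * sigma / np.sqrt(2 * n)
        rng = np.random.default_rng(7)
        failures = 0
        for _ in range(400):
            vol = CTVolume(
                values=rng.normal(-1000.0, sigma, (CROP_SIZE,) * 3), spacing=(1.0, 1.0, 1.0)
            )
            if abs(true_noise(vol, mask) - sigma) > bound:
                failures += 1
        assert failures <= 1


class TestCarina:
    def test_phantom_ridge_at_constructed_bifurcation_slice(self, noiseless_phantom):
        ph = noiseless_phantom
        mask = segment_airway(ph.volume, ph.suggested_seed_point())
        lm = detect_carina(mask)
        assert mask.to_full(VoxelIndex(0, 0, lm.ridge_slice)).k == ph.carina_slice
        # ridge point sits on the trachea axis
        axis = mask.to_crop(VoxelIndex(40, 40, 0))
        assert (lm.ridge_point.i, lm.ridge_point.j) == (axis.i, axis.j)

    def test_noisy_phantom_ridge_matches_noiseless(self, noisy_phantom, noiseless_phantom):
        seed = noisy_phantom.suggested_seed_point()
        lm_noisy = detect_carina(segment_airway(noisy_phantom.volume, seed))
        lm_clean = detect_carina(segment_airway(noiseless_phantom.volume, seed))
        assert lm_noisy.ridge_slice == lm_clean.ridge_slice

    def test_straight_cylinder_has_no_bifurcation(self, make_cylinder):
        vol = make_cylinder()
        mask = segment_airway(vol, VoxelIndex(20, 20, 20))
        with pytest.raises(NoBifurcationError):
            detect_carina(mask)

    def test_flipped_phantom_detected_with_cranial_flag(self, noiseless_phantom):
        ph = noiseless_phantom
        flipped = CTVolume(values=np.flip(ph.volume.values, axis=2).copy(), spacing=ph.volume.spacing)
        nk = ph.volume.shape[2]
        seed = ph.suggested_seed_point()
        flipped_seed = VoxelIndex(seed.i, seed.j, nk - 1 - seed.k)
        mask = segment_airway(flipped, flipped_seed)
        lm = detect_carina(mask, cranial_direction=-1)
        assert mask.to_full(VoxelIndex(0, 0, lm.ridge_slice)).k == nk - 1 - ph.carina_slice

    def test_invariant_to_in_plane_translation(self, noiseless_phantom):
        ph = noiseless_phantom
        shifted = CTVolume(values=np.roll(ph.volume.values, 3, axis=0), spacing=ph.volume.spacing)
        seed = ph.suggested_seed_point()
        lm_ref = detect_carina(segment_airway(ph.volume, seed))
        lm_shift = detect_carina(
            segment_airway(shifted, VoxelIndex(seed.i + 3, seed.j, seed.k))
        )
        assert lm_shift.ridge_slice == lm_ref.ridge_slice
        assert lm_shift.ridge_point == lm_ref.ridge_point  # crop follows the seed


class TestMeasurementCenter:
    def test_slice_offset_arithmetic(self, noiseless_phantom):
        ph = noiseless_phantom  # z spacing 0.7 mm
        mask = segment_airway(ph.volume, ph.suggested_seed_point())
        lm = detect_carina(mask)
        center = measurement_center(mask, lm, 1.0, ph.volume.spacing)
        assert center.k - ph.carina_slice == 14  # round(10 / 0.7)

    def test_exact_division_offset(self, make_cylinder):
        vol = make_cylinder(shape=(41, 41, 41), spacing=(1.0, 1.0, 1.0), radius_mm=12.0)
        mask = segment_airway(vol, VoxelIndex(20, 20, 20))
        lm = CarinaLandmark(ridge_slice=10, ridge_point=VoxelIndex(30, 30, 10))
        center = measurement_center(mask, lm, 2.0, vol.spacing)
        assert center.k == mask.to_full(VoxelIndex(0, 0, 30)).k

    def test_cylinder_centroid_on_axis_at_every_height(self, make_cylinder):
        vol = make_cylinder(shape=(41, 41, 41), spacing=(1.0, 1.0, 1.0), radius_mm=12.0)
        mask = segment_airway(vol, VoxelIndex(20, 20, 20))
        lm = CarinaLandmark(ridge_slice=15, ridge_point=VoxelIndex(30, 30, 15))
        for h in (1.0, 1.5, 2.0):
            center = measurement_center(mask, lm, h, vol.spacing)
            assert (center.i, center.j) == (20, 20)

    def test_target_slice_outside_crop_is_placement_error(self, make_cylinder):
        vol = make_cylinder()
        mask = segment_airway(vol, VoxelIndex(20, 20, 20))
        lm = CarinaLandmark(ridge_slice=55, ridge_point=VoxelIndex(30, 30, 55))
        with pytest.raises(PlacementError):
            measurement_center(mask, lm, 2.0, vol.spacing)
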