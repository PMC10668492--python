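"""View extraction, 2-D registration recovery, SSIM oracle, subtraction."""

import dataclasses

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter, rotate

from dualdelta import imagereg, phantom


def brute_ssim(a, b, window=11, sigma=1.5, k1=0.01, k2=0.03, data_range=None):
    """SSIM by explicit window loops with a Gaussian weighting kernel."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if data_range is None:
        data_range = max(a.max(), b.max()) - min(a.min(), b.min())
    win = min(window, *a.shape)
    ax = np.arange(win) - (win - 1) / 2.0
    g = np.exp(-(ax**2) / (2 * sigma**2))
    kern = np.outer(g, g)
    kern /= kern.sum()
    c1, c2 = (k1 * data_range) ** 2, (k2 * data_range) ** 2
    vals = []
    for r in range(a.shape[0] - win + 1):
        for c in range(a.shape[1] - win + 1):
            wa = a[r:r + win, c:c + win]
            wb = b[r:r + win, c:c + win]
            mu_a = (kern * wa).sum()
            mu_b = (kern * wb).sum()
            va = (kern * wa * wa).sum() - mu_a**2
            vb = (kern * wb * wb).sum() - mu_b**2
            cov = (kern * wa * wb).sum() - mu_a * mu_b
            vals.append(((2 * mu_a * mu_b + c1) * (2 * cov + c2))
                        / ((mu_a**2 + mu_b**2 + c1) * (va + vb + c2)))
    return float(np.mean(vals))


@pytest.fixture()
def structured_image(rng):
    img = gaussian_filter(rng.normal(0, 1, (64, 64)), 2.0)
    img[20:40, 25:45] += 3.0
    return img


class TestExtractViews:
    def test_centered_sphere_views(self):
        spec = phantom.PhantomSpec(radii_mm=(6.0, 6.0, 6.0),
                                   nodule_center_mm=(32.0, 32.0, 32.0), seed=0)
        pair = phantom.generate_pair(spec)
        margin = 4
        vs = imagereg.extract_views(pair.baseline_volume, pair.baseline_mask,
                                    margin=margin)
        for axis in imagereg.AXES:
            view = vs[axis]
            assert view.shape[0] == view.shape[1]
            # crop side = tight diameter + 2*margin
            assert abs(view.shape[0] - (13 + 2 * margin)) <= 1
            idx, _, _ = vs.crop_boxes[axis]
            assert idx == 32  # equatorial slice

    def test_single_voxel_mask(self):
        vol = np.zeros((10, 10, 10))
        mask = np.zeros_like(vol, dtype=bool)
        mask[5, 5, 5] = True
        vs = imagereg.extract_views(vol, mask, margin=0)
        for axis in imagereg.AXES:
            assert vs[axis].shape == (1, 1)

    def test_area_tie_takes_lowest_slice(self):
        vol = np.zeros((10, 10, 10))
        mask = np.zeros_like(vol, dtype=bool)
        mask[3, 4:6, 4:6] = True
        mask[7, 4:6, 4:6] = True  # same area, higher slice
        vs = imagereg.extract_views(vol, mask, margin=1)
        assert vs.crop_boxes["z"][0] == 3

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            imagereg.extract_views(np.zeros((5, 5, 5)),
                                   np.zeros((5, 5, 5), dtype=bool))

    def test_commutes_with_intensity_rescale(self, textured_pair):
        a = imagereg.extract_views(textured_pair.baseline_volume,
                                   textured_pair.baseline_mask)
        b = imagereg.extract_views(textured_pair.baseline_volume * 2.0 + 10.0,
                                   textured_pair.baseline_mask)
        for axis in imagereg.AXES:
            np.testing.assert_allclose(b[axis], a[axis] * 2.0 + 10.0, atol=1e-9)


class TestSSIM:
    def test_identical_images_score_one(self, structured_image):
        assert imagereg.ssim(structured_image, structured_image) == 1.0

    def test_constant_pair_scores_one(self):
        assert imagereg.ssim(np.full((16, 16), 5.0), np.full((16, 16), 5.0)) == 1.0

    def test_structure_inversion_scores_negative(self):
        # zero local mean: luminance term stays positive, the inverted
        # structure term drives the score below zero
        yy, xx = np.mgrid[:32, :32]
        a = np.sin(2 * np.pi * yy / 4.0) * np.sin(2 * np.pi * xx / 4.0)
        assert imagereg.ssim(a, -a) < 0.0
        assert imagereg.ssim(a, -a) == pytest.approx(brute_ssim(a, -a), abs=1e-8)

    def test_matches_brute_force_windowed_formula(self, rng):
        a = rng.random((20, 20))
        b = np.clip(a + rng.normal(0, 0.2, (20, 20)), 0, 1)
        got = imagereg.ssim(a, b)
        expected = brute_ssim(a, b)
        assert got == pytest.approx(expected, abs=1e-8)

    def test_small_image_uses_shrunk_window(self, rng):
        a = rng.random((8, 8))
        b = rng.random((8, 8))
        got = imagereg.ssim(a, b)
        expected = brute_ssim(a, b)  # window shrinks to 8
        assert got == pytest.approx(expected, abs=1e-8)


class TestRegister:
    def test_identity_pair(self, structured_image):
        res = imagereg.register(structured_image, structured_image,
                                "monomodal_intensity")
        assert res.ssim == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(res.translation, (0, 0), atol=0.2)

    @pytest.mark.parametrize("method", ["monomodal_intensity", "multimodal_mi"])
    def test_translation_recovery(self, structured_image, method):
        moving = np.roll(np.roll(structured_image, 3, axis=0), -5, axis=1)
        res = imagereg.register(structured_image, moving, method)
        # transform maps moving -> fixed: x shift +5, y shift -3
        tx, ty = res.translation
        assert abs(abs(tx) - 5) < 0.5 and abs(abs(ty) - 3) < 0.5
        assert res.ssim > imagereg.ssim(structured_image, moving)

    def test_rotation_recovery(self, structured_image):
        moving = rotate(structured_image, 10.0, reshape=False, order=1)
        res = imagereg.register(structured_image, moving, "monomodal_intensity")
        assert abs(abs(res.rotation_deg) - 10.0) < 1.0

    def test_keypoint_rotation_recovery(self, structured_image):
        moving = rotate(structured_image, 10.0, reshape=False, order=1)
        res = imagereg.register(structured_image, moving, "keypoint")
        assert abs(abs(res.rotation_deg) - 10.0) < 2.0

    def test_unknown_method_rejected(self, structured_image):
        with pytest.raises(ValueError, match="unknown registration"):
            imagereg.register(structured_image, structured_image, "deformable")

    def test_safeguard_never_degrades_ssim(self, rng):
        # registration of pure noise must not end worse than doing nothing
        a = rng.normal(size=(32, 32))
        b = rng.normal(size=(32, 32))
        res = imagereg.register(a, b, "monomodal_intensity")
        assert res.ssim >= imagereg.ssim(a, b) - 0.02


class TestSpineFallback:
    @pytest.fixture()
    def moving_pair(self):
        spec = phantom.PhantomSpec(
            texture_sd_hu=20.0, noise_sd_hu=3.0, seed=9,
            motion_translation_mm=(0.0, 2.0, -3.0))
        return phantom.generate_pair(spec)

    def test_zero_motion_gives_identity(self, quiet_pair):
        views = imagereg.extract_views(quiet_pair.followup_volume,
                                       quiet_pair.followup_mask)
        sf, centers = imagereg.extract_spine_views(quiet_pair.followup_volume, views)
        sm, _ = imagereg.extract_spine_views(quiet_pair.baseline_volume, views,
                                             centers=centers)
        res = imagereg.spine_fallback_register(sf["z"], sm["z"], views["z"])
        assert res.fallback_used
        np.testing.assert_allclose(res.translation, (0, 0), atol=0.3)
        assert abs(res.rotation_deg) < 0.5

    def test_translation_recovered_through_spine(self, moving_pair):
        views = imagereg.extract_views(moving_pair.followup_volume,
                                       moving_pair.followup_mask)
        sf, centers = imagereg.extract_spine_views(moving_pair.followup_volume, views)
        sm, _ = imagereg.extract_spine_views(moving_pair.baseline_volume, views,
                                             centers=centers)
        res = imagereg.spine_fallback_register(sf["z"], sm["z"], views["z"])
        # axial (z) view: in-plane motion is (y=+2, x=-3) mm
        tx, ty = res.translation
        assert abs(tx - (-3.0)) < 0.5
        assert abs(ty - 2.0) < 0.5

    def test_fallback_beats_direct_on_extreme_growth(self):
        spec = phantom.PhantomSpec(
            grid_shape=(72, 72, 72), radii_mm=(4.0, 4.0, 4.0),
            growth_rates_per_day=(0.012, 0.001, 0.012),
            texture_sd_hu=30.0, noise_sd_hu=5.0,
            motion_translation_mm=(0.0, 3.0, -3.0), interval_days=120.0, seed=13)
        pair = phantom.generate_pair(spec)
        fixed_views = imagereg.extract_views(pair.followup_volume, pair.followup_mask)
        moving_views = imagereg.extract_views(pair.baseline_volume, pair.baseline_mask)
        from skimage.transform import resize

        fixed = fixed_views["y"]
        moving = resize(moving_views["y"], fixed.shape, order=1,
                        preserve_range=True, anti_aliasing=True)
        # feature-point registration breaks down on extreme growth: it either
        # signals fallback-needed or cannot align the grown nodule well
        try:
            direct = imagereg.register(fixed, moving, "keypoint")
            keypoint_ok = direct.ssim > 0.5
        except RuntimeError:
            keypoint_ok = False
        assert not keypoint_ok
        # ... while the rigid spine still recovers the true scene motion
        sf, centers = imagereg.extract_spine_views(pair.followup_volume, fixed_views)
        sm, _ = imagereg.extract_spine_views(pair.baseline_volume, fixed_views,
                                             centers=centers)
        res = imagereg.spine_fallback_register(sf["y"], sm["y"], moving,
                                               fixed_nodule_view=fixed)
        assert res.fallback_used
        # y-view in-plane coordinates are (z, x): motion (0, +3, -3) mm maps
        # to tx = -3 px, ty = 0 px at 1 mm spacing
        tx, ty = res.translation
        assert abs(tx - (-3.0)) < 0.5
        assert abs(ty) < 0.5


class TestSubtract:
    def test_identical_inputs_zero_difference(self, structured_image):
        raw = imagereg.subtract(structured_image, structured_image, normalize=False)
        np.testing.assert_array_equal(raw, 0.0)
        norm = imagereg.subtract(structured_image, structured_image, out_size=32)
        np.testing.assert_allclose(norm, 0.5, atol=1e-12)

    def test_antisymmetry_before_rescale(self, rng):
        a, b = rng.normal(size=(16, 16)), rng.normal(size=(16, 16))
        np.testing.assert_allclose(
            imagereg.subtract(a, b, normalize=False),
            -imagereg.subtract(b, a, normalize=False))

    def test_difference_concentrates_in_growth_rim(self):
        spec = phantom.PhantomSpec(
            radii_mm=(6.0, 6.0, 6.0), growth_rates_per_day=(0.004,) * 3,
            interval_days=90.0, seed=2)
        pair = phantom.generate_pair(spec)
        z = 32
        diff = np.abs(imagereg.subtract(pair.baseline_volume[z],
                                        pair.followup_volume[z], normalize=False))
        top = diff >= np.quantile(diff[diff > 0], 0.9) if (diff > 0).any() else diff > 0
        rim_truth = pair.followup_mask[z] & ~pair.baseline_mask[z]
        inside_rim = (top & rim_truth).sum() / max(top.sum(), 1)
        assert inside_rim >= 0.8

    def test_register_pair_on_static_phantom_is_flat(self, quiet_pair):
        ds = imagereg.register_pair(quiet_pair, out_size=32)
        for axis in imagereg.AXES:
            np.testing.assert_allclose(ds.images[axis], 0.5, atol=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            imagereg.subtract(np.zeros((4, 4)), np.zeros((5, 5)))
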