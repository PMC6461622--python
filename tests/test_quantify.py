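"""En-face projection, normalisation, segmentation and VAD arithmetic."""

import numpy as np
import pytest

from iscocta import (
    ConfigError,
    DataError,
    EnFaceImage,
    QuantConfig,
    VesselMask,
    binarize,
    compute_vad,
    dice_coefficient,
    enface_projection,
    mask_flow,
    morphological_clean,
    normalize_gray_levels,
    quantify,
    smooth_flow,
)
from iscocta.quantify import VADResult


def enface(pixels):
    return EnFaceImage(pixels=np.asarray(pixels, dtype=float))


class TestProjection:
    def test_max_projection_picks_single_bright_voxel(self, rng):
        vol = np.zeros((3, 3, 10))
        bright_z = rng.integers(0, 10, (3, 3))
        vals = rng.random((3, 3)) + 1.0
        for j in range(3):
            for x in range(3):
                vol[j, x, bright_z[j, x]] = vals[j, x]
        out = enface_projection(vol, QuantConfig(projection="max"))
        np.testing.assert_allclose(out.pixels, vals)

    def test_mean_projection_of_constant_volume(self):
        out = enface_projection(np.full((2, 2, 5), 3.0), QuantConfig(projection="mean"))
        np.testing.assert_allclose(out.pixels, 3.0)

    def test_max_projection_matches_brute_force(self, rng):
        vol = rng.random((4, 5, 6))
        out = enface_projection(vol, QuantConfig(projection="max"))
        brute = np.array([[max(vol[j, x, z] for z in range(6)) for x in range(5)]
                          for j in range(4)])
        np.testing.assert_allclose(out.pixels, brute)

    def test_depth_range_restricts_projection(self, rng):
        vol = rng.random((2, 2, 8))
        out = enface_projection(vol, QuantConfig(depth_range=(2, 5)))
        np.testing.assert_allclose(out.pixels, vol[:, :, 2:5].max(axis=2))

    def test_empty_or_invalid_depth_range_rejected(self):
        with pytest.raises(ConfigError):
            QuantConfig(depth_range=(5, 5))
        with pytest.raises(DataError):
            enface_projection(np.zeros((2, 2, 4)), QuantConfig(depth_range=(0, 9)))


class TestNormalization:
    def test_fixed_point_when_percentile_already_one(self, rng):
        # top 1% of pixels pinned at 1.0, the rest below: the 99th percentile
        # is exactly 1, so rescale and clip are both no-ops
        px = rng.random((20, 20)) * 0.95
        px.flat[:5] = 1.0
        assert np.percentile(px, 99.0) == 1.0
        out = normalize_gray_levels(enface(px), QuantConfig())
        np.testing.assert_allclose(out.pixels, px, atol=1e-12)

    def test_scale_invariance(self, rng):
        px = rng.random((10, 10))
        a = normalize_gray_levels(enface(px), QuantConfig())
        b = normalize_gray_levels(enface(7.3 * px), QuantConfig())
        np.testing.assert_allclose(a.pixels, b.pixels, atol=1e-12)

    def test_ramp_rescaled_by_100th_percentile(self):
        ramp = np.linspace(0, 255, 256).reshape(16, 16)
        out = normalize_gray_levels(enface(ramp), QuantConfig(normalization_percentile=100.0))
        np.testing.assert_allclose(out.pixels, ramp / 255.0, atol=1e-12)

    def test_all_zero_image_unchanged(self):
        out = normalize_gray_levels(enface(np.zeros((4, 4))), QuantConfig())
        np.testing.assert_array_equal(out.pixels, 0.0)


class TestBinarize:
    def test_otsu_separates_two_level_image(self):
        px = np.full((20, 20), 0.1)
        px[5:10, 5:10] = 0.9
        mask = binarize(enface(px), QuantConfig(threshold_method="otsu"))
        expected = px > 0.5
        np.testing.assert_array_equal(mask.pixels, expected)

    def test_fixed_threshold_on_ramp_selects_upper_half(self):
        ramp = np.linspace(0, 1, 100).reshape(10, 10)
        cfg = QuantConfig(threshold_method="fixed", fixed_threshold=0.5)
        mask = binarize(enface(ramp), cfg)
        assert mask.vessel_pixels == (ramp > 0.5).sum()

    def test_all_zero_image_fixed_threshold(self):
        cfg = QuantConfig(threshold_method="fixed", fixed_threshold=0.5)
        mask = binarize(enface(np.zeros((4, 4))), cfg)
        assert mask.vessel_pixels == 0

    def test_otsu_on_constant_image_is_an_error(self):
        with pytest.raises(DataError, match="fixed"):
            binarize(enface(np.full((4, 4), 0.3)), QuantConfig())

    def test_unnormalised_input_rejected(self):
        with pytest.raises(DataError):
            binarize(enface(np.full((2, 2), 3.0)), QuantConfig())


class TestMorphology:
    def test_opening_removes_isolated_pixels(self):
        px = np.zeros((10, 10), dtype=bool)
        px[2, 2] = px[7, 5] = True
        out = morphological_clean(VesselMask(pixels=px), QuantConfig(morph_sequence="open"))
        assert out.vessel_pixels == 0

    def test_large_disk_blob_survives_open_close(self):
        # large structures compatible with the footprint pass unchanged
        from skimage.morphology import disk as disk_fp

        px = np.zeros((30, 30), dtype=bool)
        px[5:26, 5:26] = disk_fp(10)
        out = morphological_clean(VesselMask(pixels=px), QuantConfig())
        np.testing.assert_array_equal(out.pixels, px)

    def test_none_sequence_is_identity(self, rng):
        px = rng.random((10, 10)) > 0.5
        out = morphological_clean(VesselMask(pixels=px), QuantConfig(morph_sequence="none"))
        np.testing.assert_array_equal(out.pixels, px)

    def test_gray_smoothing_none_is_identity(self, rng):
        img = enface(rng.random((8, 8)))
        out = smooth_flow(img, QuantConfig(morph_radius=0))
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_gray_smoothing_suppresses_speckle_extremes(self, rng):
        px = np.full((20, 20), 0.5)
        px[10, 10] = 1.0  # isolated hot pixel
        out = smooth_flow(enface(px), QuantConfig())
        assert out.pixels[10, 10] == pytest.approx(0.5)


class TestVAD:
    @pytest.mark.parametrize("ones,expected", [(0, 0.0), (25, 0.25), (100, 1.0)])
    def test_vad_is_vessel_fraction(self, ones, expected):
        px = np.zeros(100, dtype=bool)
        px[:ones] = True
        result = compute_vad(VesselMask(pixels=px.reshape(10, 10)))
        assert result.vad == pytest.approx(expected)
        assert result.vessel_pixels == ones and result.total_pixels == 100

    def test_vad_monotone_as_threshold_decreases(self, rng):
        px = rng.random((30, 30))
        vads = []
        for t in [0.9, 0.7, 0.5, 0.3, 0.1]:
            cfg = QuantConfig(threshold_method="fixed", fixed_threshold=t,
                              morph_sequence="none")
            vads.append(compute_vad(binarize(enface(px), cfg)).vad)
        assert vads == sorted(vads)

    def test_adding_vessel_pixels_never_decreases_vad(self, rng):
        px = rng.random((10, 10)) > 0.7
        grown = px.copy()
        grown[0, :] = True
        assert compute_vad(VesselMask(pixels=grown)).vad >= compute_vad(VesselMask(pixels=px)).vad

    def test_result_invariant_checked(self):
        with pytest.raises(DataError):
            VADResult(vad=1.0, vessel_pixels=5, total_pixels=4,
                      mask=VesselMask(pixels=np.ones((2, 2))))


class TestMaskFlow:
    def test_all_ones_mask_is_identity(self, rng):
        img = enface(rng.random((4, 4)))
        out = mask_flow(img, VesselMask(pixels=np.ones((4, 4))))
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_all_zero_mask_blanks_image(self, rng):
        img = enface(rng.random((4, 4)))
        out = mask_flow(img, VesselMask(pixels=np.zeros((4, 4))))
        np.testing.assert_array_equal(out.pixels, 0.0)

    def test_checkerboard_mask_on_constant_image(self):
        mask = np.indices((4, 4)).sum(axis=0) % 2 == 0
        out = mask_flow(enface(np.full((4, 4), 2.0)), VesselMask(pixels=mask))
        np.testing.assert_array_equal(out.pixels, np.where(mask, 2.0, 0.0))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(DataError):
            mask_flow(enface(np.zeros((2, 2))), VesselMask(pixels=np.zeros((3, 3))))


class TestComposition:
    def test_quantify_equals_manual_steps(self, rng):
        from iscocta.quantify import smooth_flow as smooth

        vol = rng.random((8, 8, 6))
        cfg = QuantConfig(threshold_method="fixed", fixed_threshold=0.6)
        direct = quantify(vol, cfg)
        img = normalize_gray_levels(enface_projection(vol, cfg), cfg)
        img = smooth(img, cfg)
        mask = morphological_clean(binarize(img, cfg), cfg)
        manual = compute_vad(mask)
        assert direct.vad == manual.vad
        np.testing.assert_array_equal(direct.mask.pixels, manual.mask.pixels)
        np.testing.assert_array_equal(
            direct.masked_flow.pixels, mask_flow(img, mask).pixels
        )

    def test_static_volume_with_fixed_threshold_has_zero_vad(self):
        cfg = QuantConfig(threshold_method="fixed", fixed_threshold=0.5)
        result = quantify(np.zeros((6, 6, 4)), cfg)
        assert result.vad == 0.0


class TestDice:
    def test_dice_known_overlap(self):
        a = np.zeros((4, 4), dtype=bool); a[:2] = True
        b = np.zeros((4, 4), dtype=bool); b[1:3] = True
        assert dice_coefficient(a, b) == pytest.approx(0.5)

    def test_dice_empty_masks_agree_perfectly(self):
        z = np.zeros((3, 3), dtype=bool)
        assert dice_coefficient(z, z) == 1.0
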