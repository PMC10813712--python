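"""Data plumbing tests: synthetic patch generator, dense cropping and
stitching round trips, augmentation determinism, polygon rasterisation
(against both a hand oracle and shapely)."""

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from rggcunet.data import (AugmentConfig, IDENTITY_AUGMENT, SynthConfig,
                           augment, dense_crop, generate_dataset,
                           generate_srcc_patch, pad_to_multiple,
                           polygons_to_mask, stitch)


class TestSyntheticGenerator:
    def test_same_seed_is_bitwise_identical(self):
        a = generate_srcc_patch(SynthConfig(seed=11))
        b = generate_srcc_patch(SynthConfig(seed=11))
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_zero_cells_gives_negative_patch(self):
        img, mask = generate_srcc_patch(SynthConfig(seed=3, n_cells=(0, 0)))
        assert mask.sum() == 0
        assert img.shape == (128, 128, 3) and mask.shape == (128, 128)

    def test_mask_is_strictly_binary(self):
        _, mask = generate_srcc_patch(SynthConfig(seed=5))
        assert set(np.unique(mask)) <= {0, 1}

    def test_image_in_unit_range(self):
        img, _ = generate_srcc_patch(SynthConfig(seed=9))
        assert img.min() >= 0.0 and img.max() <= 1.0

    def test_foreground_fraction_within_default_bounds(self):
        fracs = [generate_srcc_patch(SynthConfig(seed=s))[1].mean()
                 for s in range(300)]
        inside = np.mean([(0.02 < f < 0.5) for f in fracs])
        assert inside >= 0.99

    def test_patch_too_small_for_cells_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(patch_size=32, cell_radius=(12.0, 24.0))

    def test_dataset_mixes_positives_and_negatives(self):
        data = generate_dataset(SynthConfig(), 16, base_seed=0,
                                negative_fraction=0.5)
        labels = [m.any() for _, m in data]
        assert any(labels) and not all(labels)


class TestDenseCropAndStitch:
    def test_exact_grid(self):
        img = np.zeros((256, 256, 3))
        patches = dense_crop(img, None, 128, 128)
        assert [off for _, _, off in patches] == [(0, 0), (0, 128),
                                                  (128, 0), (128, 128)]

    def test_single_patch_image(self):
        assert len(dense_crop(np.zeros((128, 128, 3)), None, 128, 128)) == 1

    def test_border_aligned_final_tiles(self):
        patches = dense_crop(np.zeros((200, 200, 3)), None, 128, 128)
        offs = [off for _, _, off in patches]
        assert offs == [(0, 0), (0, 72), (72, 0), (72, 72)]

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            dense_crop(np.zeros((100, 128, 3)), None, 128, 64)

    @pytest.mark.parametrize("stride", [64, 96, 128])
    def test_crop_then_stitch_is_identity_on_constant_maps(self, stride):
        H = W = 256
        prob = np.stack([np.full((H, W), 0.25), np.full((H, W), 0.75)])
        tiles = [(prob[:, r:r + 128, c:c + 128], (r, c))
                 for _, _, (r, c) in dense_crop(np.zeros((H, W, 3)), None,
                                                128, stride)]
        out = stitch(tiles, (H, W))
        np.testing.assert_allclose(out, prob, atol=1e-12)

    def test_overlap_of_identical_patches_equals_either(self, rng):
        p = rng.dirichlet(np.ones(2), size=(64, 64)).transpose(2, 0, 1)
        out = stitch([(p, (0, 0)), (p, (0, 0))], (64, 64))
        np.testing.assert_allclose(out, p, atol=1e-12)

    def test_half_overlap_matches_hand_accumulation(self, rng):
        a = rng.dirichlet(np.ones(2), size=(4, 8)).transpose(2, 0, 1)
        b = rng.dirichlet(np.ones(2), size=(4, 8)).transpose(2, 0, 1)
        out = stitch([(a, (0, 0)), (b, (0, 4))], (4, 12))
        acc = np.zeros((2, 4, 12))
        cnt = np.zeros((4, 12))
        acc[:, :, 0:8] += a
        cnt[:, 0:8] += 1
        acc[:, :, 4:12] += b
        cnt[:, 4:12] += 1
        expected = acc / cnt
        expected /= expected.sum(axis=0, keepdims=True)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_uncovered_pixels_rejected(self, rng):
        p = np.full((2, 4, 4), 0.5)
        with pytest.raises(ValueError):
            stitch([(p, (0, 0))], (8, 8))

    def test_pad_to_multiple_roundtrip(self, rng):
        img = rng.random((100, 70, 3))
        padded, orig = pad_to_multiple(img, 16)
        assert padded.shape[:2] == (112, 80)
        np.testing.assert_array_equal(padded[:100, :70], img)
        assert orig == (100, 70)


class TestAugment:
    def _patch(self, rng):
        img = rng.random((64, 64, 3))
        mask = (rng.random((64, 64)) > 0.8).astype(np.uint8)
        return img, mask

    def test_deterministic_under_fixed_seed(self, rng):
        img, mask = self._patch(rng)
        a1 = augment(img, mask, seed=42)
        a2 = augment(img, mask, seed=42)
        np.testing.assert_array_equal(a1[0], a2[0])
        np.testing.assert_array_equal(a1[1], a2[1])

    def test_identity_config_is_noop(self, rng):
        img, mask = self._patch(rng)
        out_img, out_mask = augment(img, mask, seed=0, cfg=IDENTITY_AUGMENT)
        np.testing.assert_array_equal(out_img, img)
        np.testing.assert_array_equal(out_mask, mask)

    def test_flips_move_foreground_coordinates_exactly(self, rng):
        img, mask = self._patch(rng)
        cfg = AugmentConfig(blur_prob=0.0, blur_sigma=(0, 0), hue_shift=0.0,
                            sat_range=(1, 1), rotate_deg=0.0,
                            scale_range=(1, 1), translate_frac=0.0,
                            flip_prob=1.0)
        out_img, out_mask = augment(img, mask, seed=1, cfg=cfg)
        # flip_prob=1 triggers both horizontal and vertical flips
        np.testing.assert_array_equal(out_mask, mask[::-1, ::-1])
        np.testing.assert_array_equal(out_img, img[::-1, ::-1])

    def test_mask_stays_binary_and_image_in_range(self, rng):
        img, mask = self._patch(rng)
        for seed in range(5):
            out_img, out_mask = augment(img, mask, seed=seed)
            assert set(np.unique(out_mask)) <= {0, 1}
            assert out_img.min() >= 0.0 and out_img.max() <= 1.0

    def test_geometry_applied_identically_to_image_and_mask(self, rng):
        # encode the mask in an image channel; the same warp must hit both
        mask = np.zeros((64, 64), dtype=np.uint8)
        mask[20:40, 10:30] = 1
        img = np.repeat(mask[..., None] * 1.0, 3, axis=2)
        cfg = AugmentConfig(blur_prob=0.0, blur_sigma=(0, 0), hue_shift=0.0,
                            sat_range=(1, 1))
        out_img, out_mask = augment(img, mask, seed=7, cfg=cfg)
        # nearest-neighbour mask must agree with the bilinear image away
        # from interpolated borders
        interior = (out_img[..., 0] > 0.99) | (out_img[..., 0] < 0.01)
        agree = (out_img[..., 0] > 0.5) == (out_mask > 0)
        assert agree[interior].mean() > 0.995


def brute_force_polygon_mask(polys, size):
    """Even-odd point-in-polygon at pixel centres, via shapely."""
    H, W = size
    mask = np.zeros((H, W), dtype=np.uint8)
    for poly in polys:
        P = Polygon(poly)
        for r in range(H):
            for c in range(W):
                pt = Point(c + 0.5, r + 0.5)
                if P.contains(pt) or P.touches(pt) or P.boundary.distance(pt) < 1e-9:
                    mask[r, c] = 1
    return mask


class TestPolygons:
    def test_square_covers_sixteen_pixel_centres(self):
        square = [(0, 0), (4, 0), (4, 4), (0, 4)]
        mask = polygons_to_mask([square], (8, 8))
        assert mask.sum() == 16
        assert mask[:4, :4].all()

    def test_empty_polygon_list_gives_empty_mask(self):
        assert polygons_to_mask([], (6, 6)).sum() == 0

    def test_disjoint_squares_union_adds_counts(self):
        s1 = [(0, 0), (3, 0), (3, 3), (0, 3)]
        s2 = [(5, 5), (8, 5), (8, 8), (5, 8)]
        m1 = polygons_to_mask([s1], (10, 10))
        m2 = polygons_to_mask([s2], (10, 10))
        m12 = polygons_to_mask([s1, s2], (10, 10))
        assert m12.sum() == m1.sum() + m2.sum()

    def test_matches_shapely_oracle_on_random_polygons(self, rng):
        for _ in range(5):
            n = rng.integers(3, 7)
            angles = np.sort(rng.uniform(0, 2 * np.pi, n))
            radius = rng.uniform(2, 5)
            centre = rng.uniform(5, 7, size=2)
            poly = [(centre[0] + radius * np.cos(a),
                     centre[1] + radius * np.sin(a)) for a in angles]
            mine = polygons_to_mask([poly], (12, 12))
            ref = brute_force_polygon_mask([poly], (12, 12))
            np.testing.assert_array_equal(mine, ref)

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError):
            polygons_to_mask([[(0, 0), (1, 1)]], (4, 4))
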