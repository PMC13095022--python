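"""Synthetic generation, edge ground truth, folder I/O, splits, augmentation."""

import numpy as np
import pytest
from PIL import Image
from scipy import ndimage

from dscanet.data import (ImageSample, SplitSpec, SyntheticConfig, augment,
                          derive_edge_gt, generate_sample, load_folder,
                          resize_to, save_dataset, split)


def brute_force_morph_gradient(mask: np.ndarray) -> np.ndarray:
    """Pixelwise dilation-minus-erosion with a 3×3 cross, replicate border."""
    h, w = mask.shape
    out = np.zeros_like(mask)
    for i in range(h):
        for j in range(w):
            neigh = []
            for di, dj in ((0, 0), (-1, 0), (1, 0), (0, -1), (0, 1)):
                ii = min(max(i + di, 0), h - 1)
                jj = min(max(j + dj, 0), w - 1)
                neigh.append(mask[ii, jj])
            out[i, j] = max(neigh) - min(neigh)
    return out


class TestDeriveEdgeGt:
    def test_all_zero_mask_has_empty_edge(self):
        assert derive_edge_gt(np.zeros((5, 5), dtype=np.uint8)).sum() == 0

    def test_centered_square_matches_brute_force(self):
        mask = np.zeros((7, 7), dtype=np.uint8)
        mask[2:5, 2:5] = 1
        np.testing.assert_array_equal(derive_edge_gt(mask),
                                      brute_force_morph_gradient(mask))

    def test_full_ones_mask_has_no_edge_with_replicate_border(self):
        mask = np.ones((6, 6), dtype=np.uint8)
        np.testing.assert_array_equal(derive_edge_gt(mask),
                                      brute_force_morph_gradient(mask))
        assert derive_edge_gt(mask).sum() == 0

    def test_random_masks_match_brute_force(self, rng):
        for _ in range(5):
            mask = (rng.uniform(size=(9, 8)) > 0.6).astype(np.uint8)
            np.testing.assert_array_equal(derive_edge_gt(mask),
                                          brute_force_morph_gradient(mask))

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError, match="binary"):
            derive_edge_gt(np.full((4, 4), 3))

    def test_edge_empty_iff_mask_constant(self, rng):
        for _ in range(10):
            mask = (rng.uniform(size=(8, 8)) > rng.uniform()).astype(np.uint8)
            is_const = mask.min() == mask.max()
            assert (derive_edge_gt(mask).sum() == 0) == is_const


class TestGenerateSample:
    def test_empty_polyp_range_yields_empty_masks(self):
        cfg = SyntheticConfig(image_size=32, n_polyps_range=(0, 0), seed=1)
        s = generate_sample(cfg, 0)
        assert s.mask.sum() == 0 and s.edge.sum() == 0

    def test_determinism_bit_identical(self):
        cfg = SyntheticConfig(image_size=48, seed=5)
        a, b = generate_sample(cfg, 3), generate_sample(cfg, 3)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.mask, b.mask)
        assert np.array_equal(a.edge, b.edge)

    def test_different_indices_differ(self):
        cfg = SyntheticConfig(image_size=48, seed=5)
        assert not np.array_equal(generate_sample(cfg, 0).image,
                                  generate_sample(cfg, 1).image)

    def test_single_blob_area_within_star_convex_bounds(self):
        cfg = SyntheticConfig(image_size=64, radius_range=(0.2, 0.2),
                              n_polyps_range=(1, 1), seed=7)
        area = generate_sample(cfg, 0).mask.sum()
        r = 0.2 * 64
        assert 0.5 * np.pi * r ** 2 <= area <= 2.0 * np.pi * r ** 2

    def test_image_range_and_edge_band_invariant(self):
        cfg = SyntheticConfig(image_size=64, seed=2)
        s = generate_sample(cfg, 4)
        assert s.image.min() >= 0.0 and s.image.max() <= 1.0
        # every edge pixel within a 1-pixel band of a mask transition
        grad = ndimage.morphological_gradient(s.mask, size=(3, 3))
        assert np.all(grad[s.edge == 1] > 0)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="radius_range"):
            generate_sample(SyntheticConfig(radius_range=(0.0, 0.6)), 0)


class TestFolderIO:
    def _write(self, tmp_path, n=3):
        cfg = SyntheticConfig(image_size=32, seed=9)
        samples = [generate_sample(cfg, i) for i in range(n)]
        save_dataset(samples, tmp_path)
        return samples

    def test_roundtrip_sorted_and_binary(self, tmp_path):
        written = self._write(tmp_path)
        loaded = load_folder(tmp_path, layout="kvasir")
        assert [s.sample_id for s in loaded] == sorted(s.sample_id for s in written)
        for lo, wr in zip(loaded, written):
            np.testing.assert_array_equal(lo.mask, wr.mask)
            assert set(np.unique(lo.mask)) <= {0, 1}

    def test_missing_mask_reports_orphan(self, tmp_path):
        self._write(tmp_path)
        orphan = tmp_path / "images" / "zzz_orphan.png"
        Image.fromarray(np.zeros((8, 8, 3), dtype=np.uint8)).save(orphan)
        with pytest.raises(ValueError, match="zzz_orphan"):
            load_folder(tmp_path)

    def test_grayscale_mask_thresholded_at_127(self, tmp_path):
        (tmp_path / "images").mkdir()
        (tmp_path / "masks").mkdir()
        img = np.zeros((8, 8, 3), dtype=np.uint8)
        Image.fromarray(img).save(tmp_path / "images" / "a.png")
        m = np.zeros((8, 8), dtype=np.uint8)
        m[:4] = 255
        m[4] = 120  # JPEG-like artifact below threshold
        Image.fromarray(m).save(tmp_path / "masks" / "a.png")
        s = load_folder(tmp_path)[0]
        assert s.mask[:4].all() and not s.mask[4:].any()

    def test_unknown_layout_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="layout"):
            load_folder(tmp_path, layout="nonsense")


class TestSplit:
    @pytest.mark.parametrize("n,frac,expected", [(1000, 0.8, (800, 200)),
                                                 (612, 0.75, (459, 153))])
    def test_split_sizes_match_dataset_conventions(self, n, frac, expected):
        samples = list(range(n))
        train, test = split(samples, SplitSpec(train_fraction=frac, seed=0))
        assert (len(train), len(test)) == expected

    def test_split_is_partition_and_seeded(self):
        samples = list(range(101))
        for seed in (0, 1, 2):
            spec = SplitSpec(train_fraction=0.7, seed=seed)
            tr1, te1 = split(samples, spec)
            tr2, te2 = split(samples, spec)
            assert tr1 == tr2 and te1 == te2
            assert sorted(tr1 + te1) == samples
        a, _ = split(samples, SplitSpec(0.7, seed=0))
        b, _ = split(samples, SplitSpec(0.7, seed=1))
        assert a != b

    def test_degenerate_fraction_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            split(list(range(3)), SplitSpec(train_fraction=0.01, seed=0))


class TestAugmentResize:
    def test_flips_preserve_mask_area_and_dims(self, tiny_samples):
        s = tiny_samples[0]
        rng = np.random.default_rng(3)
        for _ in range(5):
            out = augment(s, rng, max_rotation=0.0, jitter=0.0)
            assert out.shape == s.shape
            assert out.mask.sum() == s.mask.sum()
            assert set(np.unique(out.mask)) <= {0, 1}

    def test_rotation_keeps_masks_binary(self, tiny_samples):
        rng = np.random.default_rng(4)
        out = augment(tiny_samples[1], rng, max_rotation=30.0)
        assert set(np.unique(out.mask)) <= {0, 1}
        assert set(np.unique(out.edge)) <= {0, 1}

    def test_resize_identity_and_divisibility(self, tiny_samples):
        s = tiny_samples[0]
        assert resize_to(s, 64) is s
        with pytest.raises(ValueError, match="divisible by 32"):
            resize_to(s, 100)

    def test_resize_half_plane_stays_half_plane(self):
        image = np.zeros((448, 448, 3), dtype=np.float32)
        mask = np.zeros((448, 448), dtype=np.uint8)
        mask[:, 224:] = 1
        s = ImageSample(image=image, mask=mask,
                        edge=derive_edge_gt(mask), sample_id="half")
        out = resize_to(s, 224)
        assert out.shape == (224, 224)
        expected = np.zeros((224, 224), dtype=np.uint8)
        expected[:, 112:] = 1
        np.testing.assert_array_equal(out.mask, expected)
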