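"""Phantom generation, preprocessing, augmentation, folds and PNG round-trips."""

import numpy as np
import pytest
from PIL import Image

from fuzzyseg import (PhantomParams, augment, generate_phantom, make_dataset,
                      normalize_intensity, read_pair, write_pair)
from fuzzyseg.phantom import read_dataset, write_dataset


class TestGeneration:
    def test_same_seed_reproduces_sample(self, phantom_params):
        a = generate_phantom(phantom_params, seed=9)
        b = generate_phantom(phantom_params, seed=9)
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_tumor_free_phantom_has_four_classes(self, phantom_params):
        from dataclasses import replace
        p = replace(phantom_params, tumor_prob=0.0)
        s = generate_phantom(p, seed=1)
        assert set(np.unique(s.mask)) == {0, 1, 2, 3}

    def test_tumor_embedded_in_mammary_band(self, phantom_params):
        from dataclasses import replace
        p = replace(phantom_params, tumor_prob=1.0)
        p0 = replace(phantom_params, tumor_prob=0.0)
        found = 0
        for seed in range(5):
            s = generate_phantom(p, seed=seed)
            tumor = s.mask == 4
            if not tumor.any():
                continue
            found += 1
            # same seed without a tumor reproduces the bare bands: every tumor
            # pixel must have been mammary there
            bands = generate_phantom(p0, seed=seed).mask
            assert set(np.unique(bands[tumor])) == {2}
        assert found >= 4

    def test_noise_free_limit_is_piecewise_constant(self, phantom_params):
        from dataclasses import replace
        p = replace(phantom_params, speckle_strength=0.0, blur_sigma=0.0, tumor_prob=1.0)
        s = generate_phantom(p, seed=2)
        means = np.asarray(p.tissue_means)
        np.testing.assert_array_equal(np.unique(s.image),
                                      np.unique(means[np.unique(s.mask)].round()))

    def test_class_frequencies_match_band_fractions(self):
        """Averaged over 100 seeds, band areas track the configured fractions."""
        p = PhantomParams(size=128, tumor_prob=0.0)
        f1, f2, f3 = p.band_fracs
        expected = {1: f1, 2: f2 - f1, 3: f3 - f2, 0: 1 - f3}
        freqs = np.zeros(4)
        for seed in range(100):
            mask = generate_phantom(p, seed=seed).mask
            for c in range(4):
                freqs[c] += (mask == c).mean()
        freqs /= 100
        for c, exp in expected.items():
            assert freqs[c] == pytest.approx(exp, abs=0.02)

    def test_invalid_band_fractions_rejected(self):
        with pytest.raises(ValueError):
            PhantomParams(band_fracs=(0.5, 0.3, 0.8))


class TestNormalization:
    def test_endpoint_mapping(self):
        out = normalize_intensity(np.array([0.0, 127.5, 255.0]))
        np.testing.assert_allclose(out, [-1.0, 0.0, 1.0], atol=1e-15)
        assert normalize_intensity(np.array([127]))[0] == pytest.approx(-1 / 255, abs=1e-12)

    def test_roundtrip_inverse(self, rng):
        x = rng.integers(0, 256, size=(16, 16)).astype(float)
        np.testing.assert_allclose((normalize_intensity(x) + 1) * 127.5, x, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            normalize_intensity(np.array([256.0]))
        with pytest.raises(ValueError):
            normalize_intensity(np.array([-1.0]))


class TestAugmentation:
    def test_horizontal_flip_is_an_involution(self, phantom_sample):
        twice = augment(augment(phantom_sample, ["hflip"]), ["hflip"])
        np.testing.assert_array_equal(twice.image, phantom_sample.image)
        np.testing.assert_array_equal(twice.mask, phantom_sample.mask)

    def test_identity_parameters_leave_sample_unchanged(self, phantom_sample):
        out = augment(phantom_sample, [("rotation", 0.0), ("zoom", 1.0), ("hshift", 0.0)])
        np.testing.assert_array_equal(out.image, phantom_sample.image)
        np.testing.assert_array_equal(out.mask, phantom_sample.mask)

    def test_flip_preserves_class_pixel_counts_exactly(self, phantom_sample):
        out = augment(phantom_sample, ["hflip"])
        for c in range(5):
            assert (out.mask == c).sum() == (phantom_sample.mask == c).sum()

    def test_seeded_augmentation_is_deterministic(self, phantom_sample):
        a = augment(phantom_sample, ["rotation", "zoom", "shear"], seed=3)
        b = augment(phantom_sample, ["rotation", "zoom", "shear"], seed=3)
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_mask_stays_categorical_under_rotation(self, phantom_sample):
        out = augment(phantom_sample, [("rotation", 10.0)])
        assert set(np.unique(out.mask)) <= set(range(5))

    def test_unknown_op_rejected(self, phantom_sample):
        with pytest.raises(ValueError, match="unknown augmentation"):
            augment(phantom_sample, ["elastic"])


class TestDatasetAndFolds:
    def test_fold_partition_is_disjoint_and_exhaustive(self, phantom_params):
        samples, folds = make_dataset(20, phantom_params, seed=4, k_folds=10)
        assert len(samples) == 20 and len(folds) == 10
        assert all(len(f) == 2 for f in folds)
        union = np.concatenate(folds)
        assert sorted(union) == list(range(20))

    def test_partition_reproducible_from_seed(self, phantom_params):
        _, f1 = make_dataset(12, phantom_params, seed=5, k_folds=4)
        _, f2 = make_dataset(12, phantom_params, seed=5, k_folds=4)
        for a, b in zip(f1, f2):
            np.testing.assert_array_equal(a, b)

    def test_too_few_samples_rejected(self, phantom_params):
        with pytest.raises(ValueError):
            make_dataset(3, phantom_params, k_folds=10)


class TestFileIO:
    def test_pair_roundtrip_is_bit_exact(self, phantom_sample, tmp_path):
        write_pair(phantom_sample, tmp_path, "s0")
        back = read_pair(tmp_path / "s0.png", tmp_path / "s0_mask.png")
        np.testing.assert_array_equal(back.image, phantom_sample.image)
        np.testing.assert_array_equal(back.mask, phantom_sample.mask)

    def test_binary_mask_maps_to_background_and_tumor(self, tmp_path):
        img = np.zeros((8, 8), np.uint8)
        binary = np.zeros((8, 8), np.uint8)
        binary[2:5, 2:5] = 255
        Image.fromarray(img, "L").save(tmp_path / "i.png")
        Image.fromarray(binary, "L").save(tmp_path / "m.png")
        s = read_pair(tmp_path / "i.png", tmp_path / "m.png")
        assert set(np.unique(s.mask)) == {0, 4}

    def test_non_palette_mask_color_is_an_error(self, tmp_path):
        img = Image.fromarray(np.zeros((4, 4), np.uint8), "L")
        img.save(tmp_path / "i.png")
        bad = Image.fromarray(np.zeros((4, 4), np.uint8), "P")
        bad.putpalette([123, 45, 67] * 256)
        bad.save(tmp_path / "m.png")
        with pytest.raises(ValueError, match="non-palette"):
            read_pair(tmp_path / "i.png", tmp_path / "m.png")

    def test_dataset_roundtrip_with_manifest(self, phantom_params, tmp_path):
        samples, folds = make_dataset(6, phantom_params, seed=6, k_folds=3)
        manifest = write_dataset(samples, folds, tmp_path, phantom_params)
        assert len(manifest) == 6 and (tmp_path / "manifest.csv").exists()
        back, back_folds, _ = read_dataset(tmp_path)
        assert len(back) == 6 and len(back_folds) == 3
        np.testing.assert_array_equal(back[0].image, samples[0].image)
        np.testing.assert_array_equal(back[0].mask, samples[0].mask)
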