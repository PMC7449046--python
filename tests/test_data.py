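"""Patch cropping, preprocessing and augmentation contracts."""

import numpy as np
import pytest

from lprseg.data import (
    LabelError,
    PreprocessConfig,
    Sample,
    apply_brightness,
    augment,
    crop_patches,
    export_dataset,
    preprocess,
    read_image,
    read_manifest,
    read_mask,
)
from lprseg.synthetic import ClassMask, RGBImage, SceneConfig, generate_dataset


@pytest.fixture(scope="module")
def big_pair():
    """A 700x650 image/mask pair standing in for a large field photo."""
    r = np.random.default_rng(0)
    img = RGBImage(r.integers(0, 256, (700, 650, 3), dtype=np.uint8), id="big")
    mask = ClassMask(r.integers(0, 3, (700, 650)).astype(np.int64))
    return img, mask


class TestCropPatches:
    def test_sides_within_paper_bounds(self, big_pair):
        img, mask = big_pair
        cfg = PreprocessConfig(seed=1)
        for s in crop_patches(img, mask, cfg, 20):
            r0, c0, h, w = s.crop_box
            assert 150 <= h <= 600 and 150 <= w <= 600
            assert 0 <= r0 and r0 + h <= 700
            assert 0 <= c0 and c0 + w <= 650
            assert s.image.shape[:2] == (h, w)
            assert s.mask.shape == (h, w)

    def test_degenerate_range_returns_whole_image(self):
        r = np.random.default_rng(1)
        img = RGBImage(r.integers(0, 256, (600, 600, 3), dtype=np.uint8))
        mask = ClassMask(np.zeros((600, 600), np.int64))
        cfg = PreprocessConfig(crop_min=600, crop_max=600)
        (patch,) = crop_patches(img, mask, cfg, 1)
        assert patch.crop_box == (0, 0, 600, 600)
        assert np.array_equal(patch.image.pixels, img.pixels)

    def test_fixed_seed_reproduces_boxes(self, big_pair):
        img, mask = big_pair
        boxes1 = [s.crop_box for s in crop_patches(img, mask,
                                                   PreprocessConfig(seed=9), 5)]
        boxes2 = [s.crop_box for s in crop_patches(img, mask,
                                                   PreprocessConfig(seed=9), 5)]
        assert boxes1 == boxes2

    def test_too_small_image_rejected(self):
        img = RGBImage(np.zeros((100, 100, 3), np.uint8))
        with pytest.raises(ValueError, match="smaller"):
            crop_patches(img, None, PreprocessConfig(), 1)

    def test_mask_and_image_share_box(self, big_pair):
        img, mask = big_pair
        for s in crop_patches(img, mask, PreprocessConfig(seed=2), 3):
            r0, c0, h, w = s.crop_box
            assert np.array_equal(s.mask.labels,
                                  mask.labels[r0:r0 + h, c0:c0 + w])


class TestPreprocess:
    def test_shapes_and_range(self):
        r = np.random.default_rng(2)
        img = RGBImage(r.integers(0, 256, (150, 150, 3), dtype=np.uint8))
        mask = ClassMask(r.integers(0, 3, (150, 150)).astype(np.int64))
        out, mout = preprocess(Sample(img, mask), PreprocessConfig())
        assert out.shape == (256, 256, 3)
        assert out.min() >= 0.0 and out.max() <= 1.0
        assert set(np.unique(mout.labels)) <= {0, 1, 2}

    def test_extremes_normalize_exactly(self):
        zeros = RGBImage(np.zeros((64, 64, 3), np.uint8))
        ones = RGBImage(np.full((64, 64, 3), 255, np.uint8))
        cfg = PreprocessConfig(target_size=64)
        out0, _ = preprocess(Sample(zeros), cfg)
        out1, _ = preprocess(Sample(ones), cfg)
        assert np.all(out0 == 0.0)
        assert np.all(out1 == 1.0)

    def test_normalization_inverts_below_clipping(self):
        r = np.random.default_rng(3)
        img = RGBImage(r.integers(0, 256, (64, 64, 3), dtype=np.uint8))
        out, _ = preprocess(Sample(img), PreprocessConfig(target_size=64))
        assert np.array_equal(np.rint(out * 255).astype(np.uint8), img.pixels)

    def test_bad_labels_raise(self):
        img = RGBImage(np.zeros((64, 64, 3), np.uint8))
        sample = Sample(img)
        bad = ClassMask.__new__(ClassMask)  # bypass validation on purpose
        bad.labels = np.full((64, 64), 5)
        sample.mask = bad
        with pytest.raises(LabelError):
            preprocess(sample, PreprocessConfig(target_size=64))


class TestAugment:
    def _sample(self, seed=0, size=48):
        r = np.random.default_rng(seed)
        img = RGBImage(r.integers(0, 256, (size, size, 3), dtype=np.uint8))
        mask = ClassMask(r.integers(0, 3, (size, size)).astype(np.int64))
        return Sample(img, mask)

    def test_hflip_is_involution(self):
        s = self._sample()
        once = augment(s, PreprocessConfig(augmentations=()), force={"hflip"})
        twice = augment(once, PreprocessConfig(augmentations=()),
                        force={"hflip"})
        assert np.array_equal(twice.image.pixels, s.image.pixels)
        assert np.array_equal(twice.mask.labels, s.mask.labels)

    @pytest.mark.parametrize("name", ["hflip", "vflip", "rot90"])
    def test_geometric_preserves_class_counts(self, name):
        s = self._sample(4)
        out = augment(s, PreprocessConfig(augmentations=()), force={name})
        assert np.array_equal(
            np.bincount(out.mask.labels.ravel(), minlength=3),
            np.bincount(s.mask.labels.ravel(), minlength=3))

    def test_photometric_leaves_mask_untouched(self):
        s = self._sample(5)
        out = augment(s, PreprocessConfig(augmentations=()),
                      force={"hist_eq", "brightness"})
        assert np.array_equal(out.mask.labels, s.mask.labels)

    def test_brightness_clipping(self):
        assert apply_brightness(np.array([[[200, 10, 255]]], np.uint8),
                                1.3).tolist() == [[[255, 13, 255]]]

    def test_label_set_never_grows(self):
        s = self._sample(6)
        cfg = PreprocessConfig(seed=3)
        rng = np.random.default_rng(3)
        for _ in range(5):
            out = augment(s, cfg, rng=rng)
            assert set(np.unique(out.mask.labels)) <= set(
                np.unique(s.mask.labels))

    def test_unlabeled_sample_rejected(self):
        img = RGBImage(np.zeros((48, 48, 3), np.uint8))
        with pytest.raises(ValueError, match="labeled"):
            augment(Sample(img), PreprocessConfig())


def test_dataset_roundtrip_on_disk(tmp_path):
    ds = generate_dataset(SceneConfig(height=64, width=64), 2, seed=3)
    manifest = export_dataset(ds, tmp_path)
    rows = read_manifest(manifest)
    assert len(rows) == 2
    img = read_image(rows[0]["image_path"])
    mask = read_mask(rows[0]["mask_path"])
    assert np.array_equal(img.pixels, ds[0][0].pixels)
    assert np.array_equal(mask.labels, ds[0][1].labels)
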