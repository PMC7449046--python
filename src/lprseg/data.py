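"""Dataset preparation: patch cropping, augmentation, normalization, I/O.

Training samples are square-to-rectangular patches cut from large field (or
synthetic) images, resized to a fixed side length, normalized to [0, 1] and
optionally augmented.  Geometric augmentations act identically on image and
mask; photometric ones (histogram equalization, brightness) act on the image
only.  Crop boxes are 0-based, half-open ``(row0, col0, height, width)``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import imageio.v3 as iio
from skimage.transform import resize as _sk_resize
from skimage import color as _sk_color
from skimage.exposure import equalize_hist

from .synthetic import ClassMask, RGBImage

GEOMETRIC_AUGMENTATIONS = ("hflip", "vflip", "rot90")
PHOTOMETRIC_AUGMENTATIONS = ("hist_eq", "brightness")


class LabelError(ValueError):
    """Mask contains labels outside {0, 1, 2}."""


@dataclass
class Sample:
    """An (image, optional mask) pair traced back to its source crop."""

    image: RGBImage
    mask: ClassMask | None = None
    source_id: str = ""
    crop_box: tuple | None = None  # (row0, col0, height, width), half-open

    def __post_init__(self) -> None:
        if self.mask is not None and self.mask.shape != self.image.shape[:2]:
            raise ValueError("mask dimensions must match the image")


@dataclass
class PreprocessConfig:
    """Patch-preparation parameters.

    ``crop_min``/``crop_max`` bound the side lengths of random patches
    (height and width drawn independently, so rectangles are allowed);
    ``target_size`` is the square side every model input is resized to;
    intensities are always normalized to [0, 1].  Each augmentation in
    ``augmentations`` is applied independently with probability 0.5.
    """

    target_size: int = 256
    crop_min: int = 150
    crop_max: int = 600
    augmentations: tuple = ("hflip", "vflip", "rot90", "hist_eq", "brightness")
    brightness_range: tuple = (0.7, 1.3)
    seed: int = 0

    def validate(self) -> None:
        if self.crop_min > self.crop_max:
            raise ValueError("crop_min must be <= crop_max")
        if self.target_size < 32:
            raise ValueError("target_size must be >= 32")
        unknown = set(self.augmentations) - set(GEOMETRIC_AUGMENTATIONS) - set(
            PHOTOMETRIC_AUGMENTATIONS)
        if unknown:
            raise ValueError(f"unknown augmentations: {sorted(unknown)}")


def crop_patches(image: RGBImage, mask: ClassMask, config: PreprocessConfig,
                 n_patches: int, rng: np.random.Generator | None = None):
    """Cut ``n_patches`` random patches, image and mask sharing each box."""
    config.validate()
    if n_patches < 1:
        raise ValueError("n_patches must be >= 1")
    H, W = image.shape[:2]
    if H < config.crop_min or W < config.crop_min:
        raise ValueError(
            f"image {H}x{W} smaller than crop_min={config.crop_min}")
    if mask is not None and mask.shape != (H, W):
        raise ValueError("mask dimensions must match the image")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    hi_h = min(config.crop_max, H)
    hi_w = min(config.crop_max, W)
    out = []
    for _ in range(n_patches):
        ph = int(rng.integers(config.crop_min, hi_h + 1))
        pw = int(rng.integers(config.crop_min, hi_w + 1))
        r0 = int(rng.integers(0, H - ph + 1))
        c0 = int(rng.integers(0, W - pw + 1))
        sub_img = RGBImage(image.pixels[r0:r0 + ph, c0:c0 + pw].copy(),
                           id=image.id)
        sub_mask = None
        if mask is not None:
            sub_mask = ClassMask(mask.labels[r0:r0 + ph, c0:c0 + pw].copy())
        out.append(Sample(sub_img, sub_mask, source_id=image.id,
                          crop_box=(r0, c0, ph, pw)))
    return out


def preprocess(sample: Sample, config: PreprocessConfig):
    """Resize to ``target_size`` and normalize to [0, 1].

    Images are resized bilinearly; masks with nearest-neighbor so the label
    set is preserved.  Returns ``(image_float, mask_or_None)`` where
    ``image_float`` is float32 of shape (target, target, 3) in [0, 1].
    """
    config.validate()
    t = config.target_size
    img = sample.image.pixels
    if img.shape[:2] != (t, t):
        imgf = _sk_resize(img.astype(np.float32), (t, t), order=1,
                          preserve_range=True, anti_aliasing=False)
    else:
        imgf = img.astype(np.float32)
    imgf = np.clip(imgf / 255.0, 0.0, 1.0).astype(np.float32)
    maskr = None
    if sample.mask is not None:
        labels = sample.mask.labels
        if not np.isin(labels, (0, 1, 2)).all():
            raise LabelError("mask labels outside {0, 1, 2}")
        if labels.shape != (t, t):
            labels = _sk_resize(labels, (t, t), order=0, preserve_range=True,
                                anti_aliasing=False).astype(labels.dtype)
        maskr = ClassMask(labels)
    return imgf, maskr


def _equalize_luminance(img: np.ndarray) -> np.ndarray:
    """Histogram-equalize the HSV value channel, preserving hue."""
    hsv = _sk_color.rgb2hsv(img / 255.0)
    hsv[:, :, 2] = equalize_hist(hsv[:, :, 2])
    out = _sk_color.hsv2rgb(hsv) * 255.0
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def apply_brightness(img: np.ndarray, factor: float) -> np.ndarray:
    """Multiplicative brightness with clipping to [0, 255]."""
    return np.clip(np.rint(img.astype(np.float64) * factor), 0, 255).astype(
        np.uint8)


def augment(sample: Sample, config: PreprocessConfig,
            rng: np.random.Generator | None = None,
            force: set | None = None) -> Sample:
    """Randomly augment a labeled sample.

    Each configured augmentation fires independently with probability 0.5
    (``force`` makes the named ones fire deterministically, for testing).
    hflip/vflip/rot90 transform image and mask together; histogram
    equalization (on the luminance channel, hue-preserving) and brightness
    scaling touch the image only.  Equalization is applied before the
    brightness draw.
    """
    config.validate()
    if sample.mask is None:
        raise ValueError("augment requires a labeled sample")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    force = force or set()
    img = sample.image.pixels
    labels = sample.mask.labels

    def fires(name):
        if name not in config.augmentations and name not in force:
            return False
        return name in force or rng.random() < 0.5

    if fires("hflip"):
        img, labels = img[:, ::-1], labels[:, ::-1]
    if fires("vflip"):
        img, labels = img[::-1, :], labels[::-1, :]
    if fires("rot90"):
        img = np.rot90(img, axes=(0, 1))
        labels = np.rot90(labels, axes=(0, 1))
    if fires("hist_eq"):
        img = _equalize_luminance(np.ascontiguousarray(img))
    if fires("brightness"):
        factor = rng.uniform(*config.brightness_range)
        img = apply_brightness(img, factor)
    return Sample(RGBImage(np.ascontiguousarray(img), id=sample.image.id),
                  ClassMask(np.ascontiguousarray(labels)),
                  source_id=sample.source_id, crop_box=sample.crop_box)


# ---------------------------------------------------------------------------
# disk I/O: 8-bit PNGs for images, single-channel indexed PNGs for masks,
# manifest CSVs (image_path, mask_path, stage, split) for datasets
# ---------------------------------------------------------------------------

def write_image(path, image: RGBImage) -> None:
    iio.imwrite(Path(path), image.pixels)


def read_image(path) -> RGBImage:
    arr = iio.imread(Path(path))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    return RGBImage(arr[:, :, :3], id=Path(path).stem)


def write_mask(path, mask: ClassMask) -> None:
    iio.imwrite(Path(path), mask.labels.astype(np.uint8))


def read_mask(path) -> ClassMask:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return ClassMask(arr.astype(np.int64))


def write_manifest(path, rows) -> None:
    """rows: iterable of dicts with image_path, mask_path, stage, split."""
    rows = list(rows)
    fields = ["image_path", "mask_path", "stage", "split"]
    extra = [k for k in rows[0] if k not in fields] if rows else []
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields + extra)
        writer.writeheader()
        writer.writerows(rows)


def read_manifest(path):
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))


def export_dataset(dataset, out_dir, split: str = "train") -> Path:
    """Write a generated dataset to ``out_dir`` (images/, masks/, manifest)."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for image, mask, meta in dataset:
        ipath = out / "images" / f"{image.id}.png"
        mpath = out / "masks" / f"{image.id}.png"
        write_image(ipath, image)
        write_mask(mpath, mask)
        rows.append({"image_path": str(ipath), "mask_path": str(mpath),
                     "stage": meta.get("stage", ""), "split": split,
                     **{k: v for k, v in meta.items()
                        if k not in ("stage", "image_id")}})
    manifest = out / "manifest.csv"
    write_manifest(manifest, rows)
    return manifest
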