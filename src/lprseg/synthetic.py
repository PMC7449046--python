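"""Procedural rice-canopy scenes with exact 3-class ground truth.

Real grain-filling canopies are photographed from above/oblique angles and
contain three visual classes: soil/water background, elongated leaf blades
and granular panicles (clusters of grains).  This module renders simplified
but structurally faithful scenes -- curved tapered blades for leaves,
clustered overlapping grain ellipses for panicles, low-frequency soil mottle
for background -- together with the pixel-exact label mask used as ground
truth everywhere else in the package.

Growth stages follow the field convention for grain filling:

* ``GG`` -- green panicle, green leaf (early filling)
* ``YG`` -- yellow panicle, green leaf (middle filling)
* ``YY`` -- yellow panicle, yellow leaf (late filling)

Illumination nuisances (global brightness, cast shadows) perturb the image
only, never the mask, mirroring the shadow/background confusion reported for
field imagery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

BACKGROUND, LEAF, PANICLE = 0, 1, 2
CLASS_NAMES = ("background", "leaf", "panicle")

#: overlay palette: black = background, blue = leaf, green = panicle
OVERLAY_PALETTE = np.array(
    [[0, 0, 0], [0, 0, 255], [0, 255, 0]], dtype=np.uint8
)

# Plausible per-stage mean RGB for each class (8-bit units).  No quantitative
# field color statistics exist for the GG/YG/YY regimes, so these are chosen
# as representative hues: soil brown, leaf green/yellow-green, panicle
# green/straw-yellow.
STAGE_COLORS = {
    "GG": {"background": (92, 76, 58), "leaf": (62, 138, 58), "panicle": (118, 158, 84)},
    "YG": {"background": (92, 76, 58), "leaf": (62, 138, 58), "panicle": (204, 172, 88)},
    "YY": {"background": (92, 76, 58), "leaf": (168, 158, 62), "panicle": (208, 176, 92)},
}


class ConfigurationError(ValueError):
    """Raised when a SceneConfig violates its invariants."""


@dataclass
class RGBImage:
    """H x W x 3 array of 8-bit intensities, channel order R, G, B."""

    pixels: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("RGBImage requires an H x W x 3 array")
        if self.pixels.shape[0] < 32 or self.pixels.shape[1] < 32:
            raise ValueError("RGBImage must be at least 32 x 32")

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class ClassMask:
    """H x W integer labels: 0=background, 1=leaf, 2=panicle."""

    labels: np.ndarray
    class_names: tuple = CLASS_NAMES

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("ClassMask requires an H x W array")
        if self.labels.size and not np.isin(self.labels, (0, 1, 2)).all():
            raise ValueError("mask labels must be in {0, 1, 2}")

    @property
    def shape(self):
        return self.labels.shape

    def class_counts(self) -> np.ndarray:
        """Pixel count per class as a length-3 vector."""
        return np.bincount(self.labels.ravel(), minlength=3)[:3]


@dataclass
class SceneConfig:
    """Parameters of one procedural canopy scene.

    Geometric ranges are inclusive ``(low, high)`` pairs in pixels (counts
    for ``n_leaves``/``n_panicles``); ``color_spread`` is the per-channel
    standard deviation of organ colors in 8-bit units and controls class
    separability (0 = disjoint class colors, large = heavy overlap).
    ``brightness_range`` multiplies the rendered image globally;
    ``shadow_fraction`` is the approximate image fraction darkened by cast
    shadows.  Identical config + seed gives bit-identical output.
    """

    height: int = 256
    width: int = 256
    stage: str = "YG"
    n_leaves: tuple = (6, 12)
    n_panicles: tuple = (2, 5)
    leaf_length: tuple = (0.45, 0.95)   # fraction of min(H, W)
    leaf_width: tuple = (4.0, 9.0)      # blade half-width at the base, px
    leaf_curvature: tuple = (0.05, 0.30)
    grain_count: tuple = (25, 70)
    grain_radius: tuple = (2.0, 4.0)
    color_model: dict | None = None     # overrides STAGE_COLORS[stage]
    color_spread: float = 10.0
    brightness_range: tuple = (0.85, 1.15)
    shadow_fraction: float = 0.12
    shadow_factor: tuple = (0.45, 0.70)
    background_texture: float = 14.0
    panicles_on_top: bool = True
    seed: int = 0

    def colors(self) -> dict:
        return dict(STAGE_COLORS[self.stage], **(self.color_model or {}))

    def validate(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ConfigurationError("canvas must have positive area")
        if self.stage not in STAGE_COLORS:
            raise ConfigurationError(f"unknown stage {self.stage!r}")
        for name in ("n_leaves", "n_panicles", "leaf_length", "leaf_width",
                     "leaf_curvature", "grain_count", "grain_radius"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ConfigurationError(f"invalid range for {name}: {(lo, hi)}")
        if not 0.0 <= self.shadow_fraction <= 1.0:
            raise ConfigurationError("shadow_fraction must be in [0, 1]")
        for rgb in self.colors().values():
            if min(rgb) < 0 or max(rgb) > 255:
                raise ConfigurationError("color means must lie in [0, 255]")


def _draw_disks(canvas_label, canvas_color, rows, cols, radii, color, label):
    """Stamp filled disks onto the label and color canvases (in place)."""
    H, W = canvas_label.shape
    for r, c, rad in zip(rows, cols, radii):
        rad = max(float(rad), 0.5)
        r0, r1 = int(np.floor(r - rad)), int(np.ceil(r + rad)) + 1
        c0, c1 = int(np.floor(c - rad)), int(np.ceil(c + rad)) + 1
        r0, r1 = max(r0, 0), min(r1, H)
        c0, c1 = max(c0, 0), min(c1, W)
        if r0 >= r1 or c0 >= c1:
            continue
        yy = np.arange(r0, r1)[:, None] - r
        xx = np.arange(c0, c1)[None, :] - c
        inside = yy * yy + xx * xx <= rad * rad
        canvas_label[r0:r1, c0:c1][inside] = label
        canvas_color[r0:r1, c0:c1][inside] = color


def _draw_leaf(label, color, cfg: SceneConfig, rng, base_rgb, spread):
    """One blade: quadratic Bezier spine, width tapering tip-ward."""
    H, W = label.shape
    length = rng.uniform(*cfg.leaf_length) * min(H, W)
    theta = rng.uniform(0, 2 * np.pi)
    p0 = np.array([rng.uniform(0, H), rng.uniform(0, W)])
    p2 = p0 + length * np.array([np.sin(theta), np.cos(theta)])
    curv = rng.uniform(*cfg.leaf_curvature) * rng.choice((-1.0, 1.0))
    normal = np.array([np.cos(theta), -np.sin(theta)])
    p1 = (p0 + p2) / 2 + curv * length * normal
    n_pts = max(int(2 * length), 8)
    t = np.linspace(0.0, 1.0, n_pts)[:, None]
    pts = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t ** 2 * p2
    w0 = rng.uniform(*cfg.leaf_width)
    widths = w0 * (1.0 - 0.85 * t[:, 0])  # taper toward the tip
    rgb = np.clip(base_rgb + rng.normal(0, spread, 3), 0, 255)
    # slight lengthwise shading so blades are not flat-colored
    shade = 1.0 + 0.10 * np.sin(np.linspace(0, np.pi, n_pts))
    cols_rgb = np.clip(rgb[None, :] * shade[:, None], 0, 255)
    for i in range(n_pts):
        _draw_disks(label, color, [pts[i, 0]], [pts[i, 1]], [widths[i]],
                    cols_rgb[i], LEAF)


def _draw_panicle(label, color, cfg: SceneConfig, rng, base_rgb, spread):
    """One panicle: grains scattered around a drooping branch arc."""
    H, W = label.shape
    n_grain = int(rng.integers(cfg.grain_count[0], cfg.grain_count[1] + 1))
    cr, cc = rng.uniform(0, H), rng.uniform(0, W)
    theta = rng.uniform(0, 2 * np.pi)
    arc_len = rng.uniform(0.12, 0.30) * min(H, W)
    t = rng.random(n_grain)
    sway = rng.normal(0, 0.18 * arc_len, n_grain)
    rows = cr + t * arc_len * np.sin(theta) + sway * np.cos(theta)
    cols = cc + t * arc_len * np.cos(theta) - sway * np.sin(theta)
    radii = rng.uniform(cfg.grain_radius[0], cfg.grain_radius[1], n_grain)
    base = np.clip(base_rgb + rng.normal(0, spread, 3), 0, 255)
    for i in range(n_grain):
        grain_rgb = np.clip(base + rng.normal(0, 0.6 * spread, 3), 0, 255)
        _draw_disks(label, color, [rows[i]], [cols[i]], [radii[i]],
                    grain_rgb, PANICLE)


def _background(cfg: SceneConfig, rng) -> np.ndarray:
    """Low-frequency soil/water mottle around the stage background color."""
    H, W = cfg.height, cfg.width
    base = np.array(cfg.colors()["background"], dtype=np.float64)
    gh, gw = max(H // 16, 2), max(W // 16, 2)
    coarse = rng.normal(0.0, 1.0, (gh, gw))
    # bilinear upsample of the coarse field to full resolution
    ry = np.linspace(0, gh - 1, H)
    rx = np.linspace(0, gw - 1, W)
    y0 = np.clip(ry.astype(int), 0, gh - 2)
    x0 = np.clip(rx.astype(int), 0, gw - 2)
    fy, fx = (ry - y0)[:, None], (rx - x0)[None, :]
    field = ((1 - fy) * (1 - fx) * coarse[y0][:, x0]
             + (1 - fy) * fx * coarse[y0][:, x0 + 1]
             + fy * (1 - fx) * coarse[y0 + 1][:, x0]
             + fy * fx * coarse[y0 + 1][:, x0 + 1])
    img = base[None, None, :] + cfg.background_texture * field[:, :, None]
    img += rng.normal(0, 3.0, (H, W, 3))  # fine grain
    return img


def _apply_shadows(img: np.ndarray, cfg: SceneConfig, rng) -> np.ndarray:
    """Multiplicative elliptical darkening; labels are never touched."""
    H, W = img.shape[:2]
    target = cfg.shadow_fraction * H * W
    covered = 0.0
    out = img
    while covered < target:
        a = rng.uniform(0.10, 0.25) * min(H, W)
        b = a * rng.uniform(1.2, 3.0)
        phi = rng.uniform(0, np.pi)
        cr, cc = rng.uniform(0, H), rng.uniform(0, W)
        factor = rng.uniform(*cfg.shadow_factor)
        yy = np.arange(H)[:, None] - cr
        xx = np.arange(W)[None, :] - cc
        u = yy * np.cos(phi) + xx * np.sin(phi)
        v = -yy * np.sin(phi) + xx * np.cos(phi)
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        out = np.where(inside[:, :, None], out * factor, out)
        covered += inside.sum()
    return out


def generate_scene(config: SceneConfig) -> tuple[RGBImage, ClassMask]:
    """Render one canopy scene and its pixel-exact ground-truth mask.

    Organs drawn later occlude earlier ones identically in image and mask.
    By default leaves are drawn first and panicles on top (panicles overtop
    the canopy during grain filling); photometric nuisances (brightness,
    shadows) are applied to the image only.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    colors = config.colors()
    label = np.zeros((config.height, config.width), dtype=np.uint8)
    img = _background(config, rng)

    def leaves():
        n = int(rng.integers(config.n_leaves[0], config.n_leaves[1] + 1))
        for _ in range(n):
            _draw_leaf(label, img, config, rng,
                       np.asarray(colors["leaf"], float), config.color_spread)

    def panicles():
        n = int(rng.integers(config.n_panicles[0], config.n_panicles[1] + 1))
        for _ in range(n):
            _draw_panicle(label, img, config, rng,
                          np.asarray(colors["panicle"], float), config.color_spread)

    if config.panicles_on_top:
        leaves(); panicles()
    else:
        panicles(); leaves()

    img = img * rng.uniform(*config.brightness_range)
    if config.shadow_fraction > 0:
        img = _apply_shadows(img, config, rng)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    image = RGBImage(pixels, id=f"scene_{config.stage}_{config.seed}")
    return image, ClassMask(label.astype(np.int64))


def generate_dataset(config: SceneConfig, n_images: int, seed: int):
    """Generate ``n_images`` scenes with counter-derived per-image seeds.

    Per-image RNG streams come from ``SeedSequence([seed, index])`` so the
    dataset is reproducible and order-independent: image *i* is the same
    whether generated alone or as part of a batch.  Returns a list of
    ``(RGBImage, ClassMask, metadata)`` with metadata recording the stage
    and the per-image entropy.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out = []
    for i in range(n_images):
        sub = int(np.random.SeedSequence([int(seed), i]).generate_state(1)[0] % (2 ** 31))
        cfg_i = dataclasses.replace(config, seed=sub)
        image, mask = generate_scene(cfg_i)
        image.id = f"scene_{config.stage}_{seed}_{i:04d}"
        meta = {"image_id": image.id, "stage": config.stage,
                "index": i, "scene_seed": sub}
        out.append((image, mask, meta))
    return out


def overlay(mask: ClassMask) -> RGBImage:
    """Color overlay of a mask: black background, blue leaf, green panicle."""
    return RGBImage(OVERLAY_PALETTE[mask.labels], id="overlay")
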