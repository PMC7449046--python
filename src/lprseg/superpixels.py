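"""SLIC superpixel partition and region-level correction of predicted masks.

Network predictions inevitably carry local errors (shadow pixels called
background, speckle on blades).  Correcting them pixel-by-pixel is slow, so
the image is first partitioned into perceptually homogeneous superpixels by
SLIC -- k-means in combined color-position space with grid-initialized
centers spaced ``S`` apart, compactness ``C`` weighting spatial against
color distance, ``N`` iterations -- and whole regions are then reassigned,
either from an explicit edit list or by majority vote of the predicted
labels inside each region.  Color distances are measured on RGB scaled to
[0, 1], so ``C`` is image-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.segmentation import slic as _sk_slic


@dataclass
class SLICParams:
    """S: superpixel grid spacing (px); C: compactness; N: iterations."""

    S: int = 15
    C: float = 0.2
    N: int = 50

    def validate(self) -> None:
        if self.S < 2:
            raise ValueError("S must be >= 2")
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.N < 1:
            raise ValueError("N must be >= 1")


@dataclass
class SuperpixelMap:
    """Dense per-pixel region ids in [0, n_regions)."""

    regions: np.ndarray
    n_regions: int
    params: SLICParams


def slic_segment(image, params: SLICParams | None = None) -> SuperpixelMap:
    """Partition an RGB image into superpixels.

    The number of seed centers is (H/S) * (W/S); small orphan fragments are
    merged into a neighboring region (connectivity enforcement), so the
    realized region count can deviate from the grid count.  Deterministic
    for fixed input and parameters.
    """
    params = params or SLICParams()
    params.validate()
    pixels = image.pixels if hasattr(image, "pixels") else np.asarray(image)
    H, W = pixels.shape[:2]
    if H < params.S or W < params.S:
        raise ValueError(f"image {H}x{W} smaller than superpixel size "
                         f"S={params.S}")
    n_segments = max(int(round(H / params.S)) * int(round(W / params.S)), 1)
    labels = _sk_slic(
        pixels.astype(np.float64) / 255.0,
        n_segments=n_segments,
        compactness=params.C,
        max_num_iter=params.N,
        convert2lab=False,     # C is defined on [0,1] RGB distance
        enforce_connectivity=True,
        start_label=0,
        channel_axis=-1,
    )
    _, dense = np.unique(labels, return_inverse=True)
    dense = dense.reshape(labels.shape).astype(np.int64)
    return SuperpixelMap(dense, int(dense.max()) + 1, params)


def _check_mask(mask):
    labels = mask.labels if hasattr(mask, "labels") else np.asarray(mask)
    if labels.size and not np.isin(labels, (0, 1, 2)).all():
        raise ValueError("mask labels must be in {0, 1, 2}")
    return labels


def relabel_region(mask, spmap: SuperpixelMap, region_id: int,
                   new_class: int):
    """Set every pixel of one superpixel to ``new_class`` (returns a copy)."""
    from .synthetic import ClassMask

    labels = _check_mask(mask)
    if not 0 <= region_id < spmap.n_regions:
        raise ValueError(f"region_id {region_id} outside "
                         f"[0, {spmap.n_regions})")
    if new_class not in (0, 1, 2):
        raise ValueError("new_class must be in {0, 1, 2}")
    if labels.shape != spmap.regions.shape:
        raise ValueError("mask and superpixel map shapes disagree")
    out = labels.copy()
    out[spmap.regions == region_id] = new_class
    return ClassMask(out)


def apply_edits(mask, spmap: SuperpixelMap, edits):
    """Apply an ``(region_id, new_class)`` edit list sequentially."""
    out = mask
    for region_id, new_class in edits:
        out = relabel_region(out, spmap, int(region_id), int(new_class))
    return out


def majority_vote_cleanup(mask, spmap: SuperpixelMap):
    """Replace each superpixel's labels by its modal predicted class.

    Ties break toward the lower class index.  A batch analogue of manual
    region correction: removes salt noise and speckle smaller than the
    superpixel scale.
    """
    from .synthetic import ClassMask

    labels = _check_mask(mask)
    if labels.shape != spmap.regions.shape:
        raise ValueError("mask and superpixel map shapes disagree")
    counts = np.bincount(
        (spmap.regions.ravel() * 3 + labels.ravel()).astype(np.int64),
        minlength=3 * spmap.n_regions,
    ).reshape(spmap.n_regions, 3)
    modal = counts.argmax(axis=1)  # argmax takes the lowest index on ties
    return ClassMask(modal[spmap.regions])
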