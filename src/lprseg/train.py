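"""Training of the segmentation network with the multi-class focal loss.

The focal loss down-weights pixels the model already classifies well:

    L = mean over pixels of  -alpha[c] * (1 - p_c)^gamma * log(p_c)

where ``c`` is the true class and ``p_c`` its softmax probability.  With
``gamma = 0`` and uniform ``alpha`` it reduces to ordinary cross-entropy;
``gamma > 0`` focuses the gradient on hard pixels, and per-class weights
``alpha`` counter the heavy background/organ pixel imbalance of canopy
scenes (by default alpha is the inverse pixel frequency of the training
set, normalized to mean one).

Optimization uses Adam at a constant base learning rate.  Every source of
randomness (weight initialization, data order, augmentation draws) is
seeded, so identical configurations reproduce identical loss histories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .metrics import confusion, mean_iou, pixel_accuracy
from .model import FPNMask, get_weights, save_checkpoint, set_weights, softmax
from .nn import Adam

logger = logging.getLogger(__name__)

LOG_CLAMP = 1e-12


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite."""


@dataclass
class LossConfig:
    """Focal-loss hyperparameters.

    ``gamma`` is the focusing exponent (0 recovers cross-entropy); ``alpha``
    the per-class weight vector, or None to use inverse pixel frequency of
    the training labels normalized to mean 1.
    """

    gamma: float = 2.0
    alpha: tuple | None = None

    def validate(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.alpha is not None:
            a = np.asarray(self.alpha, dtype=np.float64)
            if a.shape != (3,) or (a < 0).any() or not a.any():
                raise ValueError("alpha must be 3 nonnegative weights, not all zero")


@dataclass
class TrainConfig:
    batch_size: int = 24
    learning_rate: float = 1e-3
    max_epochs: int = 50
    decay_epochs: tuple = ()     # epochs at which the rate is multiplied
    decay_factor: float = 0.1    # by this factor (constant rate if empty)
    seed: int = 0
    augment_orientation: bool = True   # random flips / 90-degree rotations
    checkpoint_every: int = 0          # 0 = only the best checkpoint
    checkpoint_path: str | None = None

    def validate(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


def focal_loss(logits: np.ndarray, target: np.ndarray,
               config: LossConfig | None = None,
               return_grad: bool = False):
    """Mean focal loss over all pixels; optionally its logit gradient.

    ``logits``: (..., 3) unnormalized scores; ``target``: integer labels of
    the matching leading shape.  The log is clamped at 1e-12 so the loss is
    always finite.
    """
    config = config or LossConfig()
    config.validate()
    logits = np.asarray(logits)
    target = np.asarray(target)
    if logits.shape[:-1] != target.shape or logits.shape[-1] != 3:
        raise ValueError(
            f"shape mismatch: logits {logits.shape} vs target {target.shape}")
    if target.size and not np.isin(target, (0, 1, 2)).all():
        raise ValueError("target labels must be in {0, 1, 2}")
    alpha = np.ones(3) if config.alpha is None else np.asarray(
        config.alpha, dtype=np.float64)
    p = softmax(logits.astype(np.float64))
    t = target.astype(np.intp)
    p_t = np.clip(np.take_along_axis(p, t[..., None], axis=-1)[..., 0],
                  LOG_CLAMP, 1.0)
    a_t = alpha[t]
    one_m = np.clip(1.0 - p_t, LOG_CLAMP, 1.0)
    logp = np.log(p_t)
    loss = float(np.mean(-a_t * one_m ** config.gamma * logp))
    if not return_grad:
        return loss
    # dL/dp_t, then chain through the softmax: dL/dz_j = c * (delta_tj - p_j)
    g = config.gamma
    dLdp = -a_t * (one_m ** g / p_t - g * one_m ** (g - 1) * logp)
    c = (dLdp * p_t / target.size)[..., None]
    dz = -c * p
    np.put_along_axis(dz, t[..., None],
                      np.take_along_axis(dz, t[..., None], axis=-1) + c,
                      axis=-1)
    return loss, dz.astype(np.float32)


def inverse_frequency_alpha(masks: np.ndarray) -> np.ndarray:
    """Per-class weights = inverse pixel frequency, normalized to mean 1."""
    counts = np.bincount(np.asarray(masks).ravel(), minlength=3)[:3]
    freq = counts / max(counts.sum(), 1)
    inv = 1.0 / np.clip(freq, 1e-8, None)
    inv[counts == 0] = 0.0
    nz = inv[inv > 0]
    return inv / nz.mean() if nz.size else np.ones(3)


def _orient_batch(xb, yb, rng):
    """Random per-sample flips and 90-degree rotations (image + mask)."""
    for i in range(xb.shape[0]):
        if rng.random() < 0.5:
            xb[i] = xb[i, :, ::-1]
            yb[i] = yb[i, :, ::-1]
        if rng.random() < 0.5:
            xb[i] = xb[i, ::-1]
            yb[i] = yb[i, ::-1]
        if rng.random() < 0.5:
            xb[i] = np.rot90(xb[i], axes=(0, 1))
            yb[i] = np.rot90(yb[i], axes=(0, 1))
    return xb, yb


def _validate_scores(model, X, Y, batch_size=8):
    cm_total = None
    for i in range(0, X.shape[0], batch_size):
        logits = model.forward(X[i:i + batch_size], train=False)
        pred = np.argmax(logits, axis=-1)
        cm = confusion(pred.ravel(), Y[i:i + batch_size].ravel())
        cm_total = cm if cm_total is None else cm_total + cm
    return pixel_accuracy(cm_total), mean_iou(cm_total)


def train(model: FPNMask, train_set, val_set=None,
          tcfg: TrainConfig | None = None, lcfg: LossConfig | None = None):
    """Mini-batch training; returns ``(model, history)``.

    ``train_set``/``val_set`` are ``(images, masks)`` tuples of arrays with
    images (N, H, W, 3) float in [0, 1] and masks (N, H, W) int.  History is
    a list of per-epoch dicts (epoch, loss, val_pa, val_miou).  The weights
    of the best epoch by validation mIoU are restored into the model at the
    end (by final train loss when there is no validation set).
    """
    tcfg = tcfg or TrainConfig()
    lcfg = lcfg or LossConfig()
    tcfg.validate()
    lcfg.validate()
    X, Y = train_set
    X = np.ascontiguousarray(X, dtype=np.float32)
    Y = np.ascontiguousarray(Y)
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    if lcfg.alpha is None:
        lcfg = LossConfig(gamma=lcfg.gamma,
                          alpha=tuple(inverse_frequency_alpha(Y)))
    rng = np.random.default_rng(tcfg.seed)
    optimizer = Adam(model.params(), lr=tcfg.learning_rate)
    history = []
    best = (-np.inf, None)
    n = X.shape[0]
    for epoch in range(tcfg.max_epochs):
        if epoch in tuple(tcfg.decay_epochs):
            optimizer.lr *= tcfg.decay_factor
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, tcfg.batch_size):
            idx = order[start:start + tcfg.batch_size]
            xb = X[idx].copy()
            yb = Y[idx].copy()
            if tcfg.augment_orientation:
                xb, yb = _orient_batch(xb, yb, rng)
            logits = model.forward(xb, train=True)
            loss, dz = focal_loss(logits, yb, lcfg, return_grad=True)
            if not np.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite loss {loss} at epoch {epoch}")
            model.zero_grad()
            model.backward(dz)
            optimizer.step()
            losses.append(loss)
        entry = {"epoch": epoch, "loss": float(np.mean(losses)),
                 "val_pa": np.nan, "val_miou": np.nan}
        score = -entry["loss"]
        if val_set is not None:
            pa, miou = _validate_scores(model, val_set[0], val_set[1])
            entry["val_pa"], entry["val_miou"] = pa, miou
            score = miou
        history.append(entry)
        logger.info("epoch %d: loss=%.4f val_pa=%.4f val_miou=%.4f",
                    epoch, entry["loss"], entry["val_pa"], entry["val_miou"])
        if score > best[0]:
            best = (score, get_weights(model))
            if tcfg.checkpoint_path:
                save_checkpoint(tcfg.checkpoint_path, model)
        if tcfg.checkpoint_every and (epoch + 1) % tcfg.checkpoint_every == 0:
            if tcfg.checkpoint_path:
                save_checkpoint(
                    str(tcfg.checkpoint_path) + f".epoch{epoch}", model)
    if best[1] is not None:
        set_weights(model, best[1])
    return model, history


def stack_samples(pairs):
    """Stack (image01, ClassMask) pairs into training arrays."""
    X = np.stack([np.asarray(img, dtype=np.float32) for img, _ in pairs])
    Y = np.stack([np.asarray(m.labels if hasattr(m, "labels") else m)
                  for _, m in pairs])
    return X, Y
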