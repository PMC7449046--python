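"""FPN-Mask: residual backbone + feature pyramid + full-resolution fusion head.

The backbone is an 18-layer-style residual network whose stage strides are
reduced so the four stages C2..C5 sit at cumulative down-sampling rates
{1, 2, 4, 8} instead of the classification-network {4, 8, 16, 32}: the stem
is a stride-1 3x3 convolution and there is no pooling before C2, so fine
spatial detail (thin leaf blades, small grains) survives to the deepest
features.  A top-down pathway with 1x1 lateral connections produces the
pyramid P2..P5, every level with the same channel width.  The fusion head
up-samples P3..P5 back to full resolution bilinearly, refines each with a
1x1 convolution, concatenates them with P2, applies a 3x3 convolution with
batch normalization and ReLU, and maps to 3 channels (background, leaf,
panicle) with a final 1x1 convolution.  The network is fully convolutional:
the same weights run on any input size divisible by 8.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .nn import Adam, BatchNorm, BilinearUp, Conv2d, NearestUp2, Param, ReLU
from .synthetic import ClassMask

N_CLASSES = 3
STAGE_STRIDES = (1, 2, 2, 2)  # C2, C3, C4, C5 -> cumulative rates 1, 2, 4, 8


class ConfigurationError(ValueError):
    pass


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``stage_channels`` is the uniform width of backbone stages and pyramid
    levels; ``backbone_depth`` the number of basic residual blocks (two 3x3
    convolutions each) per stage.  ``input_size`` is the nominal training
    resolution and must be divisible by 8 so P5 is an integer size.
    """

    input_size: int = 256
    n_classes: int = N_CLASSES
    stage_channels: int = 32
    backbone_depth: int = 2
    zero_scale_bn: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.input_size % 8 != 0:
            raise ConfigurationError("input_size must be divisible by 8")
        if self.n_classes != N_CLASSES:
            raise ConfigurationError("model is fixed at 3 classes")


class _BasicBlock:
    """Two 3x3 convolutions with identity (or strided 1x1) shortcut."""

    def __init__(self, cin, cout, stride, rng, zero_scale_bn):
        self.conv1 = Conv2d(cin, cout, 3, stride, bias=False, rng=rng)
        self.bn1 = BatchNorm(cout, zero_scale=zero_scale_bn)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, 1, bias=False, rng=rng)
        self.bn2 = BatchNorm(cout, zero_scale=zero_scale_bn)
        self.relu2 = ReLU()
        self.short = None
        if stride != 1 or cin != cout:
            self.short = Conv2d(cin, cout, 1, stride, bias=False, rng=rng)
            self.short_bn = BatchNorm(cout, zero_scale=zero_scale_bn)

    def layers(self):
        out = [self.conv1, self.bn1, self.conv2, self.bn2]
        if self.short is not None:
            out += [self.short, self.short_bn]
        return out

    def forward(self, x, train):
        y = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        y = self.bn2.forward(self.conv2.forward(y, train), train)
        if self.short is not None:
            sc = self.short_bn.forward(self.short.forward(x, train), train)
        else:
            sc = x
        return self.relu2.forward(y + sc, train)

    def backward(self, dy):
        d = self.relu2.backward(dy)
        dmain = self.bn2.backward(d)
        dmain = self.conv2.backward(dmain)
        dmain = self.conv1.backward(self.bn1.backward(self.relu1.backward(dmain)))
        if self.short is not None:
            dshort = self.short.backward(self.short_bn.backward(d))
        else:
            dshort = d
        return dmain + dshort


class FPNMask:
    """The segmentation network; see the module docstring for the layout."""

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        ch = config.stage_channels
        zs = config.zero_scale_bn
        self.stem = Conv2d(3, ch, 3, 1, bias=False, rng=rng)
        self.stem_bn = BatchNorm(ch, zero_scale=zs)
        self.stem_relu = ReLU()
        self.stages = []
        cin = ch
        for stride in STAGE_STRIDES:
            blocks = []
            for b in range(config.backbone_depth):
                blocks.append(_BasicBlock(cin, ch, stride if b == 0 else 1,
                                          rng, zs))
                cin = ch
            self.stages.append(blocks)
        self.laterals = [Conv2d(ch, ch, 1, 1, bias=True, rng=rng)
                         for _ in range(4)]
        self.up2 = [NearestUp2() for _ in range(3)]
        self.head_up = [BilinearUp(2), BilinearUp(4), BilinearUp(8)]
        self.head_conv = [Conv2d(ch, ch, 1, 1, bias=True, rng=rng)
                          for _ in range(3)]
        self.fuse_conv = Conv2d(4 * ch, 4 * ch, 3, 1, bias=False, rng=rng)
        self.fuse_bn = BatchNorm(4 * ch, zero_scale=zs)
        self.fuse_relu = ReLU()
        self.out_conv = Conv2d(4 * ch, config.n_classes, 1, 1, bias=True,
                               rng=rng)

    # -- plumbing ----------------------------------------------------------
    def _layers(self):
        out = [self.stem, self.stem_bn]
        for blocks in self.stages:
            for b in blocks:
                out += b.layers()
        out += self.laterals + self.head_conv
        out += [self.fuse_conv, self.fuse_bn, self.out_conv]
        return out

    def params(self):
        out = []
        for layer in self._layers():
            out += layer.params()
        return out

    def zero_grad(self):
        for layer in self._layers():
            layer.zero_grad()

    # -- forward / backward ------------------------------------------------
    def forward(self, x, train=False):
        """Logits of shape (N, H, W, 3) for inputs (N, H, W, 3) in [0, 1]."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[3] != 3:
            raise ValueError("expected an (N, H, W, 3) batch")
        if x.shape[1] % 8 or x.shape[2] % 8:
            raise ValueError("spatial dims must be divisible by 8")
        h = self.stem_relu.forward(
            self.stem_bn.forward(self.stem.forward(x, train), train), train)
        cs = []
        for blocks in self.stages:
            for b in blocks:
                h = b.forward(h, train)
            cs.append(h)
        c2, c3, c4, c5 = cs
        l2 = self.laterals[0].forward(c2, train)
        l3 = self.laterals[1].forward(c3, train)
        l4 = self.laterals[2].forward(c4, train)
        l5 = self.laterals[3].forward(c5, train)
        p5 = l5
        p4 = l4 + self.up2[0].forward(p5, train)
        p3 = l3 + self.up2[1].forward(p4, train)
        p2 = l2 + self.up2[2].forward(p3, train)
        h3 = self.head_conv[0].forward(self.head_up[0].forward(p3, train), train)
        h4 = self.head_conv[1].forward(self.head_up[1].forward(p4, train), train)
        h5 = self.head_conv[2].forward(self.head_up[2].forward(p5, train), train)
        f = np.concatenate([p2, h3, h4, h5], axis=3)
        g = self.fuse_relu.forward(
            self.fuse_bn.forward(self.fuse_conv.forward(f, train), train), train)
        return self.out_conv.forward(g, train)

    def backward(self, dlogits):
        ch = self.config.stage_channels
        dg = self.out_conv.backward(dlogits)
        df = self.fuse_conv.backward(
            self.fuse_bn.backward(self.fuse_relu.backward(dg)))
        dp2 = df[..., 0 * ch:1 * ch]
        dh3 = df[..., 1 * ch:2 * ch]
        dh4 = df[..., 2 * ch:3 * ch]
        dh5 = df[..., 3 * ch:4 * ch]
        dp3 = self.head_up[0].backward(self.head_conv[0].backward(dh3))
        dp4 = self.head_up[1].backward(self.head_conv[1].backward(dh4))
        dp5 = self.head_up[2].backward(self.head_conv[2].backward(dh5))
        # top-down pathway, reversed
        dl2 = dp2
        dp3 = dp3 + self.up2[2].backward(dp2)
        dl3 = dp3
        dp4 = dp4 + self.up2[1].backward(dp3)
        dl4 = dp4
        dp5 = dp5 + self.up2[0].backward(dp4)
        dl5 = dp5
        dc2 = self.laterals[0].backward(dl2)
        dc3 = self.laterals[1].backward(dl3)
        dc4 = self.laterals[2].backward(dl4)
        dc5 = self.laterals[3].backward(dl5)
        d = dc5
        for extra, blocks in zip((dc4, dc3, dc2, None), reversed(self.stages)):
            for b in reversed(blocks):
                d = b.backward(d)
            if extra is not None:
                d = d + extra
        d = self.stem.backward(self.stem_bn.backward(self.stem_relu.backward(d)))
        return d

    # -- inference helpers -------------------------------------------------
    def pyramid(self, x):
        """Evaluate P2..P5 for a batch (evaluation mode); returns a dict."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        h = self.stem_relu.forward(
            self.stem_bn.forward(self.stem.forward(x, False), False), False)
        cs = []
        for blocks in self.stages:
            for b in blocks:
                h = b.forward(h, False)
            cs.append(h)
        l2, l3, l4, l5 = (lat.forward(c, False)
                          for lat, c in zip(self.laterals, cs))
        p5 = l5
        p4 = l4 + self.up2[0].forward(p5, False)
        p3 = l3 + self.up2[1].forward(p4, False)
        p2 = l2 + self.up2[2].forward(p3, False)
        return {"P2": p2, "P3": p3, "P4": p4, "P5": p5}

    def pyramid_shapes(self, input_size: int):
        """Spatial sizes of P2..P5 for a square input (the {1,2,4,8} rates)."""
        return [(input_size // r, input_size // r) for r in (1, 2, 4, 8)]

    def predict_proba(self, x, batch_size: int = 8):
        """Per-pixel class probabilities (N, H, W, 3), evaluation mode."""
        x = np.asarray(x, dtype=np.float32)
        outs = []
        for i in range(0, x.shape[0], batch_size):
            logits = self.forward(x[i:i + batch_size], train=False)
            outs.append(softmax(logits))
        return np.concatenate(outs, axis=0)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Per-pixel softmax over the last axis (dtype-preserving)."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def build_model(config: ModelConfig) -> FPNMask:
    """Construct an FPN-Mask network from its configuration."""
    return FPNMask(config)


def predict_mask(probmap: np.ndarray) -> ClassMask:
    """Per-pixel argmax; ties resolve to the lowest class index."""
    probs = np.asarray(probmap)
    if probs.ndim != 3 or probs.shape[2] != N_CLASSES:
        raise ValueError("expected an (H, W, 3) probability map")
    return ClassMask(np.argmax(probs, axis=2).astype(np.int64))


# -- checkpointing ---------------------------------------------------------

def _state_arrays(model: FPNMask):
    arrays = {}
    for i, p in enumerate(model.params()):
        arrays[f"param_{i}"] = p.value
    for j, layer in enumerate(model._layers()):
        if isinstance(layer, BatchNorm):
            arrays[f"bn_{j}_mean"] = layer.running_mean
            arrays[f"bn_{j}_var"] = layer.running_var
    return arrays


def save_checkpoint(path, model: FPNMask) -> None:
    """Single-file checkpoint with the ModelConfig embedded."""
    arrays = _state_arrays(model)
    arrays["config_json"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> FPNMask:
    with np.load(path) as data:
        cfg = ModelConfig(**json.loads(bytes(data["config_json"]).decode()))
        model = FPNMask(cfg)
        for i, p in enumerate(model.params()):
            p.value[...] = data[f"param_{i}"]
        for j, layer in enumerate(model._layers()):
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = data[f"bn_{j}_mean"]
                layer.running_var[...] = data[f"bn_{j}_var"]
    return model


def get_weights(model: FPNMask):
    """Deep copies of all trainable values and BN statistics."""
    return {k: v.copy() for k, v in _state_arrays(model).items()}


def set_weights(model: FPNMask, weights) -> None:
    for i, p in enumerate(model.params()):
        p.value[...] = weights[f"param_{i}"]
    for j, layer in enumerate(model._layers()):
        if isinstance(layer, BatchNorm):
            layer.running_mean[...] = weights[f"bn_{j}_mean"]
            layer.running_var[...] = weights[f"bn_{j}_var"]
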