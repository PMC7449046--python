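"""Desk-scale accuracy experiment: train on synthetic canopies, evaluate.

The full-scale method was designed for large field images and long GPU
training; this module fixes a reduced protocol that runs on one CPU in
minutes while exercising every component end to end: 200 synthetic training
scenes and 50 held-out test scenes at 128 x 128 (generator defaults:
middle grain-filling colors, moderate class-color overlap, cast shadows),
a 16-channel FPN-Mask trained with the focal loss (gamma 2, inverse
frequency class weights, Adam at 1e-3, batch 24), and pooled-pixel
evaluation: per-class accuracy, PA, mIoU and macro one-vs-rest AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import confusion, mean_iou, per_class_accuracy, pixel_accuracy, roc_auc
from .model import ModelConfig, build_model
from .synthetic import SceneConfig, generate_dataset
from .train import LossConfig, TrainConfig, train

#: training phases (epochs, learning rate) of the reduced protocol.  Each
#: phase restarts the Adam moment estimates from the best weights so far
#: (a warm restart); the restarts, more than the final rate drop, are what
#: push the last boundary errors out on this task (see docs/methods.md).
DEFAULT_PHASES = ((6, 1e-3), (4, 1e-3), (4, 3e-4))

N_TRAIN, N_VAL, N_TEST = 200, 20, 50
IMAGE_SIZE = 128
STAGE_CHANNELS = 16


@dataclass
class BenchmarkResult:
    panicle_accuracy: float
    leaf_accuracy: float
    background_accuracy: float
    pixel_accuracy: float
    mean_iou: float
    auc_macro: float
    auc_per_class: np.ndarray
    n_test_pixels: int
    history: list


def _split(scene: SceneConfig, n: int, seed: int):
    ds = generate_dataset(scene, n, seed)
    X = np.stack([d[0].pixels for d in ds]).astype(np.float32) / 255.0
    Y = np.stack([d[1].labels for d in ds])
    return X, Y


def scaled_accuracy_benchmark(seed: int = 1,
                              phases=DEFAULT_PHASES) -> BenchmarkResult:
    """Run the reduced train/evaluate experiment with every RNG seeded."""
    seed = int(seed) % (2 ** 31 - 10)
    scene = SceneConfig(height=IMAGE_SIZE, width=IMAGE_SIZE)
    X_train, Y_train = _split(scene, N_TRAIN, seed)
    X_val, Y_val = _split(scene, N_VAL, seed + 10_000)
    X_test, Y_test = _split(scene, N_TEST, seed + 20_000)

    model = build_model(ModelConfig(input_size=IMAGE_SIZE,
                                    stage_channels=STAGE_CHANNELS,
                                    backbone_depth=2, seed=seed))
    history = []
    for k, (epochs, lr) in enumerate(phases):
        tcfg = TrainConfig(batch_size=24, learning_rate=lr,
                           max_epochs=epochs, seed=seed + k)
        model, hist = train(model, (X_train, Y_train), (X_val, Y_val),
                            tcfg, LossConfig(gamma=2.0))
        history += hist

    probs = model.predict_proba(X_test)
    preds = np.argmax(probs, axis=-1)
    cm = confusion(preds.ravel(), Y_test.ravel())
    acc = per_class_accuracy(cm)
    _, aucs, macro = roc_auc([probs[i] for i in range(len(probs))],
                             [Y_test[i] for i in range(len(Y_test))])
    return BenchmarkResult(
        panicle_accuracy=float(acc[2]),
        leaf_accuracy=float(acc[1]),
        background_accuracy=float(acc[0]),
        pixel_accuracy=pixel_accuracy(cm),
        mean_iou=mean_iou(cm),
        auc_macro=macro,
        auc_per_class=aucs,
        n_test_pixels=int(cm.sum()),
        history=history,
    )
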