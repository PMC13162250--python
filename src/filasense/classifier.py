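"""The emission-event CNN: architecture, training loop, and prediction.

The network is four convolutional blocks (3x3 kernels, same padding, each
conv followed by batch normalisation and ReLU): two convs of 32, 64 and 128
filters in blocks 1-3, each block ending in a 2x2/stride-2 max pool that
takes a 512x512 input down through 256 and 128 to 64, then a single 256-
filter conv.  The head is flatten -> dropout(0.5) -> 128-unit ReLU layer ->
4-way linear layer -> softmax.  Inputs are RGB scaled to [0, 1].

Training follows the study protocol: Adam at 1e-4 with a 0.1 learning-rate
drop every 30 epochs, 60 epochs, minibatch 8, shuffling every epoch, random
augmentation of each training image, cross-entropy loss, validation checks
every 100 iterations, and the best-validation-accuracy weights kept.

The ``small`` profile (128x128 input, half filters, 30 epochs) is the
desk-scale configuration used throughout the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .constants import CLASSES
from .nn import (Adam, BatchNorm, Conv2D, Dense, Dropout, Flatten, MaxPool2,
                 ReLU, Sequential, cross_entropy, piecewise_lr, softmax,
                 tune_allocator)
from .preprocess import AugmentPolicy, augment

__all__ = ["ArchitectureSpec", "TrainConfig", "ClassProbabilities",
           "build_network", "train", "predict", "GRADCAM_LAYER"]

log = logging.getLogger(__name__)

#: second ReLU activation of the third convolutional block — the saliency tap
GRADCAM_LAYER = "relu3_2"


@dataclass(frozen=True)
class ArchitectureSpec:
    """Layer plan of the CNN; ``small()`` is the desk-scale profile."""

    input_side: int = 512
    block_filters: tuple[int, int, int, int] = (32, 64, 128, 256)
    convs_per_block: tuple[int, int, int, int] = (2, 2, 2, 1)
    dense_units: int = 128
    dropout: float = 0.5
    n_classes: int = len(CLASSES)

    @classmethod
    def small(cls) -> "ArchitectureSpec":
        return cls(input_side=128, block_filters=(16, 32, 64, 128))

    @property
    def feature_side(self) -> int:
        return self.input_side // 8  # three 2x2 pools


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    lr_drop_every: int = 30
    lr_factor: float = 0.1
    epochs: int = 60
    batch_size: int = 8
    val_every: int = 100           # iterations between validation checks
    augment: AugmentPolicy | None = field(default_factory=AugmentPolicy)
    seed: int = 0

    @classmethod
    def small(cls, **kw) -> "TrainConfig":
        return cls(epochs=30, **kw)


@dataclass
class ClassProbabilities:
    """Softmax outputs; predicted class is the argmax, confidence its value."""

    probabilities: np.ndarray          # (n, 4)
    classes: tuple[str, ...] = CLASSES

    @property
    def predicted_index(self) -> np.ndarray:
        return self.probabilities.argmax(axis=1)

    @property
    def predicted(self) -> list[str]:
        return [self.classes[i] for i in self.predicted_index]

    @property
    def confidence(self) -> np.ndarray:
        return self.probabilities.max(axis=1)


def build_network(spec: ArchitectureSpec | None = None, seed: int = 0) -> Sequential:
    """Instantiate the CNN with seeded uniform fan-in initial weights."""
    spec = spec or ArchitectureSpec()
    if spec.input_side % 8 != 0:
        raise ValueError("input side must be divisible by 8 (three 2x2 pools)")
    rng = np.random.default_rng(seed)
    layers: list = []
    in_ch = 3
    for b, (filters, n_convs) in enumerate(zip(spec.block_filters,
                                               spec.convs_per_block), start=1):
        for j in range(1, n_convs + 1):
            layers.append((f"conv{b}_{j}", Conv2D(in_ch, filters, rng=rng)))
            layers.append((f"bn{b}_{j}", BatchNorm(filters)))
            layers.append((f"relu{b}_{j}", ReLU()))
            in_ch = filters
        if b <= 3:
            layers.append((f"pool{b}", MaxPool2()))
    feat = spec.feature_side ** 2 * spec.block_filters[-1]
    layers += [
        ("flatten", Flatten()),
        ("dropout", Dropout(spec.dropout, rng=np.random.default_rng(rng.integers(2 ** 31)))),
        ("fc1", Dense(feat, spec.dense_units, rng=rng)),
        ("relu_fc", ReLU()),
        ("fc2", Dense(spec.dense_units, spec.n_classes, rng=rng)),
    ]
    model = Sequential(layers)
    model.spec = spec
    return model


def _to_float01(images) -> np.ndarray:
    x = np.asarray(images)
    if x.dtype == np.uint8:
        x = x.astype(np.float32) / 255.0
    return x.astype(np.float32, copy=False)


def _split_arrays(manifest, split: str) -> tuple[np.ndarray, np.ndarray]:
    rows = manifest.select(split)
    if manifest.images is None:
        raise ValueError("manifest carries no in-memory images")
    x = np.stack([_to_float01(manifest.images[i]) for i in rows["image_id"]])
    y = np.array([CLASSES.index(lbl) for lbl in rows["label"]])
    return x, y


def train(model: Sequential, manifest, cfg: TrainConfig | None = None) -> dict:
    """Train on a manifest's train split, checkpointing on validation accuracy.

    Returns a history dict (per-check loss/accuracy, learning rates, the
    best checkpoint's accuracy); the model is left holding the best weights.
    """
    cfg = cfg or TrainConfig()
    tune_allocator()
    x_train, y_train = _split_arrays(manifest, "train")
    x_val, y_val = _split_arrays(manifest, "val")
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("manifest needs non-empty train and val splits")
    for i, cls in enumerate(CLASSES):
        if not (y_train == i).any():
            log.warning("class %r absent from the train split", cls)

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    history: dict = {"iteration": [], "val_loss": [], "val_accuracy": [],
                     "train_loss": [], "lr_per_epoch": [], "best_val_accuracy": 0.0}
    best_state = model.state_dict()
    best_acc = -1.0
    iteration = 0

    def val_check() -> None:
        nonlocal best_acc, best_state
        probs = model.predict_proba(x_val, batch=cfg.batch_size)
        acc = float((probs.argmax(axis=1) == y_val).mean())
        loss = float(-np.log(np.clip(probs[np.arange(len(y_val)), y_val],
                                     1e-12, None)).mean())
        history["iteration"].append(iteration)
        history["val_loss"].append(loss)
        history["val_accuracy"].append(acc)
        if acc > best_acc:
            best_acc = acc
            best_state = model.state_dict()

    for epoch in range(cfg.epochs):
        opt.lr = piecewise_lr(cfg.learning_rate, epoch, cfg.lr_drop_every,
                              cfg.lr_factor)
        history["lr_per_epoch"].append(opt.lr)
        order = rng.permutation(len(x_train))
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch = x_train[idx]
            if cfg.augment is not None:
                batch = np.stack([
                    augment(im, cfg.augment, seed=int(rng.integers(2 ** 31)))
                    for im in batch])
            logits = model.forward(batch, mode="train")
            loss, dlogits = cross_entropy(logits, y_train[idx])
            model.backward(dlogits)
            opt.step(model.gradients())
            history["train_loss"].append(loss)
            iteration += 1
            if iteration % cfg.val_every == 0:
                val_check()
    val_check()
    model.load_state_dict(best_state)
    history["best_val_accuracy"] = best_acc
    return history


def predict(model: Sequential, images: np.ndarray,
            batch: int = 8) -> ClassProbabilities:
    """Softmax class probabilities in inference mode (dropout off,
    running batch-norm statistics); deterministic and idempotent."""
    x = _to_float01(images)
    if x.ndim == 3:
        x = x[None]
    side = getattr(model, "spec", None)
    if side is not None and x.shape[1:3] != (side.input_side, side.input_side):
        raise ValueError(f"expected {side.input_side}x{side.input_side} input, "
                         f"got {x.shape[1:3]}")
    return ClassProbabilities(model.predict_proba(x, batch=batch))
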