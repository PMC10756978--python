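"""The CNN classifier applied to the rendered GSN images.

Architecture (fixed up to sizes): three convolutional blocks, each with 32
filters of size 3x3 and ReLU, followed by 2x2 max-pooling (stride 1 for
the first two blocks, stride 2 for the third), batch normalization and
dropout (rates 0.20 / 0.20 / 0.50); then flatten and a dense softmax head.
Trained with Adam on categorical cross-entropy (default learning rate
0.05, 80 epochs, 70/30 train/test split).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .io_preprocess import ValidationError


@dataclass
class ConvBlockSpec:
    filters: int = 32
    kernel: int = 3
    pool_size: int = 2
    pool_stride: int = 1
    dropout: float = 0.2


@dataclass
class CNNArchitecture:
    """Three conv blocks + dense softmax head (see module docstring)."""

    blocks: list[ConvBlockSpec] = field(default_factory=lambda: [
        ConvBlockSpec(pool_stride=1, dropout=0.20),
        ConvBlockSpec(pool_stride=1, dropout=0.20),
        ConvBlockSpec(pool_stride=2, dropout=0.50),
    ])


@dataclass
class TrainConfig:
    learning_rate: float = 0.05
    epochs: int = 80
    train_fraction: float = 0.70
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValidationError("train_fraction must be in (0, 1)")
        if self.learning_rate < 0:
            raise ValidationError("learning_rate must be >= 0")
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")


def conv_stack_output_shape(
    height: int, width: int, arch: CNNArchitecture | None = None
) -> tuple[int, int, int]:
    """(C, H, W) after the conv/pool stack, by the layer arithmetic.

    Valid convolution maps H -> H - k + 1; pooling maps
    H -> (H - size) // stride + 1.  Raises if any stage underflows.
    """
    arch = arch or CNNArchitecture()
    h, w, c = height, width, 3
    for i, blk in enumerate(arch.blocks):
        if h < blk.kernel or w < blk.kernel:
            raise ValidationError(f"input too small at conv block {i + 1}: {h}x{w}")
        h, w = h - blk.kernel + 1, w - blk.kernel + 1
        if h < blk.pool_size or w < blk.pool_size:
            raise ValidationError(f"input too small at pool block {i + 1}: {h}x{w}")
        h = (h - blk.pool_size) // blk.pool_stride + 1
        w = (w - blk.pool_size) // blk.pool_stride + 1
        c = blk.filters
    return (c, h, w)


class CNNClassifier:
    """NumPy CNN over NHWC float images in [0, 1]."""

    def __init__(self, input_shape: tuple[int, int, int], n_classes: int,
                 arch: CNNArchitecture | None = None, seed: int = 0) -> None:
        h, w, c = input_shape
        if c != 3:
            raise ValidationError("expected 3-channel (RGB) input")
        arch = arch or CNNArchitecture()
        cf, hf, wf = conv_stack_output_shape(h, w, arch)  # validates size
        rng = np.random.default_rng(seed)
        self.input_shape = input_shape
        self.n_classes = n_classes
        self.arch = arch
        self.layers: list[nn.Layer] = []
        cin = c
        for blk in arch.blocks:
            self.layers.append(nn.Conv2D(cin, blk.filters, blk.kernel, rng))
            self.layers.append(nn.MaxPool2D(blk.pool_size, blk.pool_stride))
            self.layers.append(nn.BatchNorm2D(blk.filters))
            self.layers.append(nn.Dropout(blk.dropout))
            cin = blk.filters
        self.layers.append(nn.Flatten())
        self.layers.append(nn.Dense(cf * hf * wf, n_classes, rng))

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def _to_nchw(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=np.float32)
        if x.ndim != 4 or x.shape[1:] != self.input_shape:
            raise ValidationError(
                f"images shape {x.shape[1:]} does not match model input {self.input_shape}"
            )
        return np.ascontiguousarray(x.transpose(0, 3, 1, 2))

    def forward(self, images: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Class-probability rows (softmax over the dense head logits)."""
        x = self._to_nchw(images)
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return nn.softmax(x)

    def backward(self, probs: np.ndarray, onehot: np.ndarray) -> None:
        # Gradient of mean cross-entropy through the softmax.
        dout = ((probs - onehot) / probs.shape[0]).astype(np.float32)
        for layer in reversed(self.layers):
            dout = layer.backward(dout)


def build_cnn(
    input_shape: tuple[int, int, int],
    n_classes: int,
    arch: CNNArchitecture | None = None,
    seed: int = 0,
) -> CNNClassifier:
    """Construct the (seeded) CNN; raises if the image is too small."""
    return CNNClassifier(input_shape, n_classes, arch=arch, seed=seed)


def split_train_test(
    n_items: int,
    labels: np.ndarray,
    train_fraction: float = 0.70,
    seed: int = 0,
    stratified: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive index split; stratified keeps class proportions.

    Train size is round(fraction * n) — per class when stratified.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.shape[0] != n_items:
        raise ValidationError("labels length does not match item count")
    if not 0 < train_fraction < 1:
        raise ValidationError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    if not stratified:
        perm = rng.permutation(n_items)
        n_train = int(round(train_fraction * n_items))
        return np.sort(perm[:n_train]), np.sort(perm[n_train:])
    train_parts, test_parts = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        perm = rng.permutation(idx.shape[0])
        n_train = int(round(train_fraction * idx.shape[0]))
        if n_train == 0:
            raise ValidationError(f"class {cls} has no training items after the split")
        train_parts.append(idx[perm[:n_train]])
        test_parts.append(idx[perm[n_train:]])
    return np.sort(np.concatenate(train_parts)), np.sort(np.concatenate(test_parts))


def train_cnn(
    model: CNNClassifier,
    train_images: np.ndarray,
    train_labels: np.ndarray,
    config: TrainConfig,
    val_images: np.ndarray | None = None,
    val_labels: np.ndarray | None = None,
) -> list[dict]:
    """Adam / categorical cross-entropy training loop.

    Returns a per-epoch history (loss and accuracy averaged over the
    epoch's batches, plus validation metrics when a validation set is
    given).  Deterministic given the config seed.
    """
    y = np.asarray(train_labels, dtype=int)
    n = y.shape[0]
    if n == 0:
        raise ValidationError("empty training set")
    onehot = np.eye(model.n_classes, dtype=np.float32)[y]
    opt = nn.Adam(model.params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history: list[dict] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, config.batch_size):
            sel = order[start:start + config.batch_size]
            probs = model.forward(train_images[sel], training=True, rng=rng)
            loss = nn.cross_entropy(probs, onehot[sel])
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch + 1}")
            losses.append(loss * sel.shape[0])
            correct += int((probs.argmax(axis=1) == y[sel]).sum())
            model.backward(probs, onehot[sel])
            opt.step(model.grads)
        row = {
            "epoch": epoch + 1,
            "loss": float(np.sum(losses) / n),
            "accuracy": correct / n,
        }
        if val_images is not None and val_labels is not None:
            vp = predict(model, val_images)
            vy = np.asarray(val_labels, dtype=int)
            row["val_loss"] = nn.cross_entropy(vp, np.eye(model.n_classes, dtype=np.float32)[vy])
            row["val_accuracy"] = float((vp.argmax(axis=1) == vy).mean())
        history.append(row)
    return history


def predict(model: CNNClassifier, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Per-sample class-probability rows (dropout off, running BN stats)."""
    images = np.asarray(images, dtype=np.float32)
    outs = [
        model.forward(images[i:i + batch_size], training=False)
        for i in range(0, images.shape[0], batch_size)
    ]
    return np.concatenate(outs, axis=0)
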