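"""Compact shuffle-block gesture classifier.

A small ShuffleNetV2-style convolutional network over the
(channels x 18-feature) window map: stem convolution, max pooling, two
stages of shuffle blocks (a stride-2 downsampling "Unit Two" followed
by stride-1 "Unit One" blocks with channel split and shuffle), global
average pooling and two fully connected layers ending in a 9-way
softmax.  Grouped pointwise convolutions with channel shuffle keep the
parameter count low while still fusing information across EMG
channels, which is why this family of networks suits multichannel
gesture recognition on modest datasets.

Training, evaluation (confusion matrix / per-class recall) and the 2-D
t-SNE embedding of penultimate activations live here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .config import GESTURE_CODES, child_rng
from .nn import channel_shuffle  # re-export; part of this module's surface

__all__ = [
    "ModelConfig", "EvalReport", "ShuffleBlockNet",
    "split_dataset", "channel_shuffle", "build_model", "train",
    "evaluate", "embed_2d",
]


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters (defaults CPU-sized)."""

    stem_filters: int = 24
    stage_widths: tuple = (48, 96)
    blocks_per_stage: int = 2      # Unit One blocks after each Unit Two
    groups: int = 2                # channel-shuffle groups
    penultimate: int = 64          # first fully connected layer width
    n_classes: int = 9
    epochs: int = 150
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.n_classes != len(GESTURE_CODES):
            raise ValueError(f"n_classes must be {len(GESTURE_CODES)}")
        for w in self.stage_widths:
            if w % 2:
                raise ValueError("stage widths must be even (channel split)")
        if self.stem_filters % self.groups:
            raise ValueError("stem filters must be divisible by groups")


@dataclass
class EvalReport:
    """Held-out evaluation: accuracy, 9x9 confusion matrix, recalls."""

    accuracy: float
    confusion: np.ndarray          # rows = true class, cols = predicted
    per_class_recall: np.ndarray
    history: dict = field(default_factory=dict)

    def __post_init__(self):
        tr = np.trace(self.confusion)
        total = self.confusion.sum()
        if total and not np.isclose(self.accuracy, tr / total):
            raise ValueError("accuracy inconsistent with confusion-matrix trace")


def split_dataset(n_or_tensor, fraction: float = 0.8, seed: int = 0):
    """Random shuffled train/test split of window indices.

    Accepts a window count or a FeatureTensor.  Returns
    ``(train_idx, test_idx)``; disjoint, exhaustive, deterministic
    given *seed*.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    n = n_or_tensor if isinstance(n_or_tensor, (int, np.integer)) \
        else n_or_tensor.n_windows
    perm = child_rng(seed, "split").permutation(n)
    n_train = int(round(fraction * n))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


class _UnitOne(nn.Layer):
    """Stride-1 shuffle block: channel split, transform one half,
    concatenate, channel shuffle."""

    def __init__(self, ch: int, groups: int, rng):
        super().__init__()
        if ch % 2:
            raise ValueError("Unit One needs an even channel count")
        half = ch // 2
        self.branch = nn.Sequential(
            nn.Conv2d(half, half, 1, rng=rng), nn.BatchNorm2d(half), nn.ReLU(),
            nn.DepthwiseConv2d(half, 3, 1, 1, rng=rng), nn.BatchNorm2d(half),
            nn.Conv2d(half, half, 1, rng=rng), nn.BatchNorm2d(half), nn.ReLU(),
        )
        self.shuffle = nn.ChannelShuffle(groups)
        self.half = half
        self.params = self.branch.params
        self.grads = self.branch.grads

    def forward(self, x, train=True):
        x1, x2 = x[:, :self.half], x[:, self.half:]
        self._x1_shape = x1.shape
        out = np.concatenate([x1, self.branch.forward(x2, train)], axis=1)
        return self.shuffle.forward(out, train)

    def backward(self, dout):
        d = self.shuffle.backward(dout)
        d1, d2 = d[:, :self.half], d[:, self.half:]
        return np.concatenate([d1, self.branch.backward(d2)], axis=1)


class _UnitTwo(nn.Layer):
    """Stride-2 downsampling shuffle block; doubles the width."""

    def __init__(self, in_ch: int, out_ch: int, groups: int, rng):
        super().__init__()
        if out_ch % 2:
            raise ValueError("Unit Two needs an even output width")
        half = out_ch // 2
        self.b1 = nn.Sequential(
            nn.DepthwiseConv2d(in_ch, 3, 2, 1, rng=rng), nn.BatchNorm2d(in_ch),
            nn.Conv2d(in_ch, half, 1, rng=rng), nn.BatchNorm2d(half), nn.ReLU(),
        )
        self.b2 = nn.Sequential(
            nn.Conv2d(in_ch, half, 1, rng=rng), nn.BatchNorm2d(half), nn.ReLU(),
            nn.DepthwiseConv2d(half, 3, 2, 1, rng=rng), nn.BatchNorm2d(half),
            nn.Conv2d(half, half, 1, rng=rng), nn.BatchNorm2d(half), nn.ReLU(),
        )
        self.shuffle = nn.ChannelShuffle(groups)
        self.half = half
        self.params = self.b1.params + self.b2.params
        self.grads = self.b1.grads + self.b2.grads

    def forward(self, x, train=True):
        out = np.concatenate(
            [self.b1.forward(x, train), self.b2.forward(x, train)], axis=1)
        return self.shuffle.forward(out, train)

    def backward(self, dout):
        d = self.shuffle.backward(dout)
        return self.b1.backward(d[:, :self.half]) \
            + self.b2.backward(d[:, self.half:])


class ShuffleBlockNet:
    """The full network; input (batch, n_emg_channels, 18) feature maps."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = child_rng(cfg.seed, "model-init")
        layers: list[nn.Layer] = [
            nn.Conv2d(1, cfg.stem_filters, 3, 1, 1, rng=rng),
            nn.BatchNorm2d(cfg.stem_filters), nn.ReLU(),
            nn.MaxPool2x2(),
        ]
        ch = cfg.stem_filters
        for width in cfg.stage_widths:
            layers.append(_UnitTwo(ch, width, cfg.groups, rng))
            for _ in range(cfg.blocks_per_stage):
                layers.append(_UnitOne(width, cfg.groups, rng))
            ch = width
        layers.append(nn.GlobalAvgPool())
        self.backbone = nn.Sequential(*layers)
        self.fc1 = nn.Dense(ch, cfg.penultimate, rng=rng)
        self.fc1_act = nn.ReLU()
        self.fc2 = nn.Dense(cfg.penultimate, cfg.n_classes, rng=rng)
        self.params = self.backbone.params + self.fc1.params + self.fc2.params
        self.grads = self.backbone.grads + self.fc1.grads + self.fc2.grads

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))

    @staticmethod
    def _as_maps(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 3:                      # (batch, channels, 18)
            x = x[:, None]                   # single-plane map
        if x.ndim != 4:
            raise ValueError("expected (batch, channels, features) input")
        return x

    def forward(self, x: np.ndarray, train: bool = True,
                return_penultimate: bool = False):
        h = self.backbone.forward(self._as_maps(x), train)
        pen = self.fc1.forward(h, train)
        out = self.fc2.forward(self.fc1_act.forward(pen, train), train)
        if return_penultimate:
            return out, pen
        return out

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.fc2.backward(dlogits)
        d = self.fc1.backward(self.fc1_act.backward(d))
        self.backbone.backward(d)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return nn.softmax(self.forward(x, train=False))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    def penultimate(self, x: np.ndarray) -> np.ndarray:
        """First fully connected layer output (pre-activation)."""
        _, pen = self.forward(x, train=False, return_penultimate=True)
        return pen


def build_model(cfg: ModelConfig | None = None) -> ShuffleBlockNet:
    """Construct the (untrained) network for *cfg*."""
    return ShuffleBlockNet(cfg or ModelConfig())


def train(model: ShuffleBlockNet, x_train: np.ndarray, y_train: np.ndarray,
          cfg: ModelConfig | None = None) -> dict:
    """Minimize cross-entropy with Adam; returns the history dict.

    History records per-epoch mean loss and training accuracy.
    Deterministic given ``cfg.seed``.
    """
    cfg = cfg or model.cfg
    y_train = np.asarray(y_train, dtype=int)
    if x_train.shape[0] == 0:
        raise ValueError("empty training set")
    if np.unique(y_train).size < 2:
        raise ValueError("training set contains a single class")
    if y_train.min() < 0 or y_train.max() >= cfg.n_classes:
        raise ValueError(f"labels must lie in 0..{cfg.n_classes - 1}")
    rng = child_rng(cfg.seed, "train-shuffle")
    opt = nn.Adam(model.params, model.grads, lr=cfg.learning_rate)
    loss_fn = nn.SoftmaxCrossEntropy()
    n = x_train.shape[0]
    history = {"loss": [], "accuracy": []}
    for _epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            logits = model.forward(xb, train=True)
            losses.append(loss_fn.forward(logits, yb))
            correct += int((logits.argmax(axis=1) == yb).sum())
            opt.zero_grad()
            model.backward(loss_fn.backward())
            opt.step()
        history["loss"].append(float(np.mean(losses)))
        history["accuracy"].append(correct / n)
    return history


def evaluate(model: ShuffleBlockNet, x_test: np.ndarray, y_test: np.ndarray,
             history: dict | None = None) -> EvalReport:
    """Accuracy, confusion matrix (true rows) and per-class recall."""
    y_test = np.asarray(y_test, dtype=int)
    if x_test.shape[0] == 0:
        raise ValueError("empty test set")
    pred = model.predict(x_test)
    k = model.cfg.n_classes
    confusion = np.zeros((k, k), dtype=int)
    np.add.at(confusion, (y_test, pred), 1)
    row = confusion.sum(axis=1)
    recall = np.divide(np.diag(confusion), row, out=np.zeros(k), where=row > 0)
    return EvalReport(
        accuracy=float(np.trace(confusion) / confusion.sum()),
        confusion=confusion,
        per_class_recall=recall,
        history=history or {},
    )


def embed_2d(activations: np.ndarray, seed: int = 0,
             perplexity: float = 30.0) -> np.ndarray:
    """t-SNE embedding of penultimate activations to 2 dimensions."""
    from sklearn.manifold import TSNE

    activations = np.asarray(activations, dtype=float)
    n = activations.shape[0]
    if n < 10:
        raise ValueError("need at least 10 points to embed")
    if perplexity >= n:
        raise ValueError(f"perplexity {perplexity} requires more than {n} points")
    tsne = TSNE(n_components=2, perplexity=perplexity, init="pca",
                random_state=int(seed))
    return tsne.fit_transform(activations)
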