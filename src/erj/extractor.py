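"""Convolutional feature extractors of configurable depth.

Three presets mirror truncations of the VGG-16 layout — shallow
(4 conv / 1 pool), middle (7 conv / 2 pool) and deep (13 conv / 4 pool) —
plus a ``tiny`` preset (2 conv / 1 pool) sized so that the full selection
loop runs in minutes on one CPU.  Channel widths follow the VGG doubling
schedule scaled from a configurable base width.

The embedding of an image is the global average pool of the final
convolutional stage (after its ReLU), so the embedding dimension equals the
final channel count regardless of input size.  A dense softmax head on top
of the embedding is used for fine-tuning and evaluation; ``embed`` runs the
network below the head and never updates parameters.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_model import LabeledDataset
from .nn import (
    Adam,
    Conv3x3,
    Dense,
    GlobalAvgPool,
    MaxPool2,
    ReLU,
    Sequential,
    softmax_cross_entropy,
)

# Stage layout per preset: integers are width multipliers for a conv layer,
# "P" is a 2x2 max pool.  Full-scale presets are VGG-16 prefixes.
_PRESET_LAYOUT: dict[str, list] = {
    "tiny": [1, 2, "P"],
    "shallow": [1, 1, "P", 2, 2],
    "middle": [1, 1, "P", 2, 2, "P", 4, 4, 4],
    "deep": [1, 1, "P", 2, 2, "P", 4, 4, 4, "P", 8, 8, 8, "P", 8, 8, 8],
}

_PRESET_BASE_WIDTH = {"tiny": 8, "shallow": 64, "middle": 64, "deep": 64}


@dataclass
class ExtractorSpec:
    """Architecture + training-head description of a feature extractor."""

    depth_preset: str = "tiny"
    input_shape: tuple[int, int, int] = (32, 32, 3)
    head_classes: int = 2
    base_width: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_preset not in _PRESET_LAYOUT:
            raise ValueError(
                f"unknown depth_preset {self.depth_preset!r}; "
                f"choose from {sorted(_PRESET_LAYOUT)}"
            )
        if self.base_width is None:
            self.base_width = _PRESET_BASE_WIDTH[self.depth_preset]
        if self.head_classes < 2:
            raise ValueError("head_classes must be >= 2")

    @property
    def layout(self) -> list:
        return list(_PRESET_LAYOUT[self.depth_preset])

    @property
    def conv_layers(self) -> int:
        return sum(1 for s in self.layout if s != "P")

    @property
    def pool_layers(self) -> int:
        return sum(1 for s in self.layout if s == "P")

    @property
    def embedding_dim(self) -> int:
        last = [s for s in self.layout if s != "P"][-1]
        return last * self.base_width


@dataclass
class EmbeddingMatrix:
    """n x d matrix of extractor outputs, row-aligned with sample ids."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError("row count != id count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("embedding matrix contains non-finite values")

    @property
    def dim(self) -> int:
        return int(self.values.shape[1])

    def __len__(self) -> int:
        return int(self.values.shape[0])


class Extractor:
    """A built (optionally fine-tuned) extractor with its classification head.

    Use :func:`build_extractor` rather than constructing directly.
    """

    def __init__(self, spec: ExtractorSpec):
        h, w, c = spec.input_shape
        if c != 3:
            raise ValueError("input_shape must have 3 channels")
        stride = 2 ** spec.pool_layers
        if h % stride or w % stride or h < stride or w < stride:
            raise ValueError(
                f"input {h}x{w} incompatible with {spec.pool_layers} pooling "
                f"halvings (needs multiples of {stride})"
            )
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        layers = []
        c_in = 3
        for item in spec.layout:
            if item == "P":
                layers.append(MaxPool2())
            else:
                c_out = item * spec.base_width
                layers.append(Conv3x3(c_in, c_out, rng))
                layers.append(ReLU())
                c_in = c_out
        layers.append(GlobalAvgPool())
        self._embed_depth = len(layers)  # embedding = output of GAP
        layers.append(Dense(spec.embedding_dim, spec.head_classes, rng))
        self.net = Sequential(layers)
        self._opt: Adam | None = None
        self.training_log: list[dict] = []

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Checkpoint parameters with the spec embedded."""
        state = {
            "spec": self.spec,
            "params": [p.copy() for p in self.net.parameters()],
            "training_log": self.training_log,
        }
        with open(path, "wb") as fh:
            pickle.dump(state, fh)

    @staticmethod
    def load(path: str | Path) -> "Extractor":
        with open(path, "rb") as fh:
            state = pickle.load(fh)
        handle = Extractor(state["spec"])
        for p, saved in zip(handle.net.parameters(), state["params"]):
            p[...] = saved
        handle.training_log = state["training_log"]
        return handle

    def parameter_hash(self) -> int:
        return hash(tuple(p.tobytes() for p in self.net.parameters()))

    # -- inference --------------------------------------------------------
    def _check_images(self, data: LabeledDataset) -> np.ndarray:
        if data.payload_kind != "image":
            raise ValueError("extractor expects image payloads")
        if tuple(data.payload.shape[1:]) != tuple(self.spec.input_shape):
            raise ValueError(
                f"payload shape {data.payload.shape[1:]} != spec input_shape "
                f"{self.spec.input_shape}"
            )
        return data.payload

    def logits(self, images: np.ndarray, batch: int = 256) -> np.ndarray:
        out = [self.net.forward(images[i : i + batch])
               for i in range(0, images.shape[0], batch)]
        return np.concatenate(out, axis=0)

    def predict(self, data: LabeledDataset) -> np.ndarray:
        return np.argmax(self.logits(self._check_images(data)), axis=1)


def build_extractor(spec: ExtractorSpec) -> Extractor:
    """Build an extractor with deterministic seeded initialization."""
    return Extractor(spec)


def finetune(
    handle: Extractor,
    base: LabeledDataset,
    epochs: int,
    seed: int,
    lr: float = 0.01,
    batch_size: int = 32,
) -> Extractor:
    """Train head + backbone on the base data; returns the same handle.

    Deterministic given ``seed`` (fixed shuffles, pure NumPy arithmetic).
    With ``epochs == 0`` parameters are untouched.  Appends per-epoch mean
    loss and training accuracy to ``handle.training_log``.
    """
    if epochs < 0:
        raise ValueError("epochs must be >= 0")
    if len(base) == 0:
        raise ValueError("base dataset is empty")
    if base.n_classes != handle.spec.head_classes:
        raise ValueError(
            f"base has {base.n_classes} classes but head expects "
            f"{handle.spec.head_classes}"
        )
    if epochs == 0:
        return handle
    images = handle._check_images(base)
    labels = base.labels
    rng = np.random.default_rng(seed)
    if handle._opt is None:
        handle._opt = Adam(handle.net.parameters(), lr=lr)
    opt = handle._opt
    n = images.shape[0]
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        correct = 0
        for start in range(0, n, batch_size):
            rows = order[start : start + batch_size]
            logits = handle.net.forward(images[rows])
            loss, dlogits = softmax_cross_entropy(logits, labels[rows])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    "lower the learning rate"
                )
            handle.net.backward(dlogits)
            opt.step(handle.net.gradients())
            losses.append(loss * rows.size)
            correct += int(np.sum(np.argmax(logits, axis=1) == labels[rows]))
        handle.training_log.append(
            {"epoch": len(handle.training_log),
             "loss": float(np.sum(losses) / n),
             "train_accuracy": correct / n}
        )
    return handle


def embed(handle: Extractor, data: LabeledDataset, batch: int = 256) -> EmbeddingMatrix:
    """Embeddings (pooled final-stage features) for every sample, in order.

    Pure function of (parameters, data): no parameter updates occur.
    """
    images = handle._check_images(data)
    rows = [handle.net.forward(images[i : i + batch], upto=handle._embed_depth)
            for i in range(0, images.shape[0], batch)]
    values = np.concatenate(rows, axis=0)
    if not np.all(np.isfinite(values)):
        raise FloatingPointError("non-finite embedding values")
    return EmbeddingMatrix(sample_ids=list(data.sample_ids), values=values)
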