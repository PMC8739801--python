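"""Dataset container, deterministic stratified splitting, and I/O.

A :class:`LabeledDataset` holds either image tensors (n, h, w, 3) in [0, 1]
or feature vectors (n, d), together with string sample identifiers, integer
class labels and the class-name vocabulary.  Identifiers are stable strings
(file-path derived for folder datasets) so that selection manifests survive
re-loading a dataset.

Splitting is stratified per class with floor rounding: the train (or base)
side receives ``floor(fraction * class_count)`` samples and the remainder
goes to test (or pool).  Membership is drawn with a seeded generator, so a
``(dataset, spec)`` pair always produces the same split.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

logger = logging.getLogger(__name__)

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}


@dataclass
class LabeledDataset:
    """Samples with labels; payload is images or feature vectors.

    Parameters
    ----------
    sample_ids:
        Ordered, unique string identifiers, one per sample.
    payload:
        ``(n, h, w, 3)`` float array in [0, 1] for ``payload_kind="image"``,
        or ``(n, d)`` float array for ``payload_kind="feature"``.
    labels:
        ``(n,)`` integer class indices into ``class_names``.
    class_names:
        Ordered label vocabulary.
    """

    sample_ids: list[str]
    payload: np.ndarray
    labels: np.ndarray
    class_names: list[str]
    payload_kind: str = "feature"

    def __post_init__(self) -> None:
        self.payload = np.asarray(self.payload, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.sample_ids = list(self.sample_ids)
        if self.payload_kind not in ("image", "feature"):
            raise ValueError(f"unknown payload_kind {self.payload_kind!r}")
        if self.payload_kind == "image" and self.payload.ndim != 4:
            raise ValueError("image payload must be (n, h, w, 3)")
        if self.payload_kind == "feature" and self.payload.ndim != 2:
            raise ValueError("feature payload must be (n, d)")
        n = len(self.sample_ids)
        if self.payload.shape[0] != n or self.labels.shape[0] != n:
            raise ValueError(
                f"length mismatch: {n} ids, {self.payload.shape[0]} payload rows, "
                f"{self.labels.shape[0]} labels"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample_ids")
        if n and (self.labels.min() < 0 or self.labels.max() >= len(self.class_names)):
            raise ValueError("labels outside class_names vocabulary")

    def __len__(self) -> int:
        return len(self.sample_ids)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def index_of(self, sample_id: str) -> int:
        return self._id_index()[sample_id]

    def _id_index(self) -> dict[str, int]:
        idx = getattr(self, "_idx_cache", None)
        if idx is None or len(idx) != len(self.sample_ids):
            idx = {s: i for i, s in enumerate(self.sample_ids)}
            self._idx_cache = idx
        return idx

    def subset(self, ids: Sequence[str]) -> "LabeledDataset":
        """Sub-dataset with the given ids, in the given order."""
        index = self._id_index()
        missing = [s for s in ids if s not in index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:10]}")
        rows = [index[s] for s in ids]
        return LabeledDataset(
            sample_ids=list(ids),
            payload=self.payload[rows],
            labels=self.labels[rows],
            class_names=list(self.class_names),
            payload_kind=self.payload_kind,
        )

    def class_counts(self) -> dict[str, int]:
        counts = np.bincount(self.labels, minlength=self.n_classes)
        return {name: int(c) for name, c in zip(self.class_names, counts)}

    def concat(self, other: "LabeledDataset") -> "LabeledDataset":
        if self.class_names != other.class_names:
            raise ValueError("class vocabularies differ")
        if self.payload_kind != other.payload_kind:
            raise ValueError("payload kinds differ")
        return LabeledDataset(
            sample_ids=self.sample_ids + other.sample_ids,
            payload=np.concatenate([self.payload, other.payload], axis=0),
            labels=np.concatenate([self.labels, other.labels]),
            class_names=list(self.class_names),
            payload_kind=self.payload_kind,
        )


@dataclass
class SplitSpec:
    """Fractions and seed controlling the two-stage split.

    ``train_fraction`` divides the full dataset into train/test (default 8:2);
    ``base_fraction_of_train`` divides train into base/pool (default 1:9).
    """

    train_fraction: float = 0.8
    base_fraction_of_train: float = 0.1
    per_class: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("train_fraction", "base_fraction_of_train"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")


def _split_ids(
    dataset: LabeledDataset, fraction: float, seed: int, stage: str
) -> tuple[list[str], list[str]]:
    """Stratified floor split of sample ids; first part gets floor(fraction*n_c)."""
    rng = np.random.default_rng(seed)
    first: list[str] = []
    second: list[str] = []
    ids = np.asarray(dataset.sample_ids, dtype=object)
    for c, name in enumerate(dataset.class_names):
        rows = np.flatnonzero(dataset.labels == c)
        if rows.size == 0:
            continue
        n_first = int(np.floor(fraction * rows.size))
        if n_first == 0:
            raise ValueError(
                f"{stage}: fraction {fraction} yields zero samples for class {name!r}"
            )
        if n_first == rows.size:
            raise ValueError(
                f"{stage}: fraction {fraction} leaves class {name!r} with an "
                "empty complement"
            )
        perm = rng.permutation(rows.size)
        chosen = rows[perm[:n_first]]
        rest = rows[perm[n_first:]]
        first.extend(ids[np.sort(chosen)])
        second.extend(ids[np.sort(rest)])
    return first, second


def stratified_split(
    dataset: LabeledDataset, spec: SplitSpec
) -> tuple[LabeledDataset, LabeledDataset]:
    """Split into train/test, per class, with floor rounding on the train side.

    With 1000 samples per class and ``train_fraction=0.8`` each class
    contributes exactly 800 train and 200 test samples.
    """
    counts = dataset.class_counts()
    thin = [n for n, c in counts.items() if c < 2]
    if thin:
        raise ValueError(f"classes with fewer than 2 samples: {thin}")
    train_ids, test_ids = _split_ids(
        dataset, spec.train_fraction, spec.seed, "train/test split"
    )
    return dataset.subset(train_ids), dataset.subset(test_ids)


def base_pool_split(
    train: LabeledDataset, spec: SplitSpec
) -> tuple[LabeledDataset, LabeledDataset]:
    """Split train into base/pool; base gets floor(base_fraction * class count).

    800 train per class at the default fraction 0.1 gives 80 base + 720 pool.
    """
    if len(train) == 0:
        raise ValueError("train dataset is empty")
    # Offset the seed so base membership is independent of the train/test draw.
    base_ids, pool_ids = _split_ids(
        train, spec.base_fraction_of_train, spec.seed + 1, "base/pool split"
    )
    return train.subset(base_ids), train.subset(pool_ids)


def load_image_folder(
    path: str | Path, resize_to: tuple[int, int] = (224, 224)
) -> LabeledDataset:
    """Load a ``root/<class>/<image>`` folder into an image dataset.

    Images are decoded to RGB, resized with bilinear interpolation and scaled
    to [0, 1].  Undecodable files are skipped with a logged warning; an empty
    class directory is an error.  Sample ids are relative POSIX paths.
    """
    root = Path(path)
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise ValueError(f"no class subdirectories under {root}")
    class_names = [d.name for d in class_dirs]
    h, w = resize_to
    ids: list[str] = []
    images: list[np.ndarray] = []
    labels: list[int] = []
    n_skipped = 0
    for ci, d in enumerate(class_dirs):
        files = sorted(
            f for f in d.iterdir() if f.suffix.lower() in _IMAGE_SUFFIXES
        )
        loaded_any = False
        for f in files:
            try:
                with Image.open(f) as im:
                    arr = np.asarray(
                        im.convert("RGB").resize((w, h), Image.BILINEAR),
                        dtype=np.float64,
                    )
            except (UnidentifiedImageError, OSError) as exc:
                n_skipped += 1
                logger.warning("skipping undecodable image %s: %s", f, exc)
                continue
            ids.append(f.relative_to(root).as_posix())
            images.append(arr / 255.0)
            labels.append(ci)
            loaded_any = True
        if not loaded_any:
            raise ValueError(f"class directory {d} contains no decodable images")
    if n_skipped:
        logger.warning("skipped %d undecodable images under %s", n_skipped, root)
    return LabeledDataset(
        sample_ids=ids,
        payload=np.stack(images),
        labels=np.asarray(labels),
        class_names=class_names,
        payload_kind="image",
    )


def save_manifest(splits: Mapping[str, Sequence[str]], path: str | Path) -> None:
    """Write named sets of sample ids as a JSON mapping split-name -> id list."""
    payload = {name: list(ids) for name, ids in splits.items()}
    Path(path).write_text(json.dumps(payload, indent=1))


def load_manifest(
    path: str | Path, dataset: LabeledDataset | None = None
) -> dict[str, list[str]]:
    """Read a manifest; if ``dataset`` is given, validate that all ids exist."""
    splits = json.loads(Path(path).read_text())
    splits = {name: list(ids) for name, ids in splits.items()}
    if dataset is not None:
        known = set(dataset.sample_ids)
        unknown = [s for ids in splits.values() for s in ids if s not in known]
        if unknown:
            raise KeyError(f"manifest references unknown sample ids: {unknown}")
    return splits


def save_embeddings(
    path: str | Path,
    sample_ids: Sequence[str],
    labels: Sequence[int],
    values: np.ndarray,
) -> None:
    """Write an embedding table.

    ``.csv``/``.tsv`` produce delimited text with columns
    ``sample_id, label, f0..f{d-1}``; ``.npz`` produces a columnar binary
    archive (arrays ``sample_ids``, ``labels``, ``values``).
    """
    path = Path(path)
    values = np.asarray(values)
    if path.suffix == ".npz":
        np.savez_compressed(
            path,
            sample_ids=np.asarray(sample_ids, dtype=str),
            labels=np.asarray(labels, dtype=np.int64),
            values=values,
        )
        return
    sep = "\t" if path.suffix == ".tsv" else ","
    df = pd.DataFrame(values, columns=[f"f{j}" for j in range(values.shape[1])])
    df.insert(0, "label", np.asarray(labels, dtype=np.int64))
    df.insert(0, "sample_id", list(sample_ids))
    df.to_csv(path, sep=sep, index=False)


def load_embeddings(
    path: str | Path, class_names: list[str] | None = None
) -> LabeledDataset:
    """Read an embedding table written by :func:`save_embeddings`."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            ids = [str(s) for s in z["sample_ids"]]
            labels = z["labels"]
            values = z["values"]
    else:
        sep = "\t" if path.suffix == ".tsv" else ","
        df = pd.read_csv(path, sep=sep)
        ids = df["sample_id"].astype(str).tolist()
        labels = df["label"].to_numpy()
        values = df.drop(columns=["sample_id", "label"]).to_numpy(dtype=np.float64)
    if class_names is None:
        class_names = [str(c) for c in range(int(np.max(labels)) + 1)]
    return LabeledDataset(
        sample_ids=ids,
        payload=values,
        labels=labels,
        class_names=class_names,
        payload_kind="feature",
    )
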