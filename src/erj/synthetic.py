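"""Synthetic labeled fixtures with controllable redundancy and hidden sub-modes.

Real image pools mix near-duplicates of what a model has already seen with
genuinely novel appearances (new pose, background, colour morph of the same
class).  The generators here reproduce that structure with known ground
truth:

* **feature level** — each class is a Gaussian mixture: ``modes_per_class``
  centers at pairwise distance >= ``mode_separation``, isotropic noise of
  scale ``noise_scale``, and a ``duplication_rate`` fraction of rows that
  are exact copies of earlier rows.
* **image level** — small RGB images where the class determines a shape
  motif and each (class, mode) pair has its own colour scheme (motif colour
  and background level), plus per-instance position jitter and pixel noise.
  A model never shown a mode's colour scheme has no basis to classify it,
  which is exactly the situation novelty-driven selection should exploit.

``make_base_pool_with_hidden_modes`` performs the standard two-stage split
(train/test then base/pool) but draws the base only from non-hidden modes,
so the pool provably contains both redundant (in-range) and novel
(out-of-range) samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import LabeledDataset, SplitSpec, base_pool_split, stratified_split

_MOTIFS = ("square", "cross", "hstripes", "vstripes", "diamond", "frame")


@dataclass
class FixtureSpec:
    """Parameters of a synthetic fixture; fully determines it with ``seed``."""

    n_classes: int = 6
    modes_per_class: int = 4
    samples_per_class: int = 100
    hidden_modes_per_class: int = 1
    mode_separation: float = 3.0
    noise_scale: float = 0.5
    duplication_rate: float = 0.0
    level: str = "feature"
    feature_dim: int = 32
    image_shape: tuple[int, int] = (16, 16)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.hidden_modes_per_class < self.modes_per_class):
            raise ValueError("hidden_modes_per_class must be < modes_per_class")
        if not (0.0 <= self.duplication_rate < 1.0):
            raise ValueError("duplication_rate must be in [0, 1)")
        if self.mode_separation <= 0:
            raise ValueError("mode_separation must be positive")
        if self.level not in ("feature", "image"):
            raise ValueError("level must be 'feature' or 'image'")


def _assign_modes(spec: FixtureSpec) -> np.ndarray:
    """Cycle modes 0..M-1 over the originals of one class (balanced)."""
    n_orig = spec.samples_per_class - _n_duplicates(spec)
    return np.arange(n_orig) % spec.modes_per_class


def _n_duplicates(spec: FixtureSpec) -> int:
    return int(round(spec.duplication_rate * spec.samples_per_class))


def _draw_centers(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    """(n_classes, modes, d) mode centers, all pairwise >= mode_separation apart.

    Visible-mode centers are Gaussian draws.  Hidden-mode centers (the last
    ``hidden_modes_per_class`` of each class) are additionally pushed outside
    the visible centers' span in a few randomly chosen dimensions, so hidden
    sub-modes occupy feature-space territory the visible modes provably do
    not — ground-truth novelty in the support sense, not merely a distant
    point within the occupied region.
    """
    total = spec.n_classes * spec.modes_per_class
    n_vis = spec.modes_per_class - spec.hidden_modes_per_class
    scale = max(spec.mode_separation, 1.0)
    for _ in range(200):
        centers = rng.normal(0.0, scale, size=(total, spec.feature_dim))
        centers = centers.reshape(spec.n_classes, spec.modes_per_class, -1)
        if spec.hidden_modes_per_class:
            vis = centers[:, :n_vis].reshape(-1, spec.feature_dim)
            lo, hi = vis.min(axis=0), vis.max(axis=0)
            n_out = max(1, spec.feature_dim // 8)
            for c in range(spec.n_classes):
                for m in range(n_vis, spec.modes_per_class):
                    dims = rng.choice(spec.feature_dim, size=n_out, replace=False)
                    for j in dims:
                        offset = rng.uniform(0.5, 1.5) * spec.mode_separation
                        if rng.integers(0, 2):
                            centers[c, m, j] = hi[j] + offset
                        else:
                            centers[c, m, j] = lo[j] - offset
        flat = centers.reshape(total, -1)
        diff = flat[:, None, :] - flat[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=-1))
        np.fill_diagonal(dist, np.inf)
        if dist.min() >= spec.mode_separation:
            return centers
    raise RuntimeError(
        f"could not place {total} mode centers at separation "
        f"{spec.mode_separation} in {spec.feature_dim} dimensions; "
        "increase feature_dim or reduce mode_separation"
    )


def generate_feature_fixture(
    spec: FixtureSpec,
) -> tuple[LabeledDataset, np.ndarray]:
    """Gaussian-mixture feature dataset plus per-sample mode labels.

    Within each class, originals cycle through the modes; duplicated rows
    (exact copies of earlier originals of the same class) are appended after
    the originals they copy.  Deterministic given ``spec.seed``.
    """
    if spec.level != "feature":
        raise ValueError("spec.level must be 'feature'")
    rng = np.random.default_rng(spec.seed)
    centers = _draw_centers(spec, rng)
    ids: list[str] = []
    rows: list[np.ndarray] = []
    labels: list[int] = []
    modes: list[int] = []
    n_dup = _n_duplicates(spec)
    for c in range(spec.n_classes):
        mode_assign = _assign_modes(spec)
        noise = rng.normal(
            0.0, spec.noise_scale, size=(mode_assign.size, spec.feature_dim)
        )
        originals = centers[c, mode_assign] + noise
        for i, (x, m) in enumerate(zip(originals, mode_assign)):
            ids.append(f"c{c}_s{i:04d}")
            rows.append(x)
            labels.append(c)
            modes.append(int(m))
        if n_dup:
            src = rng.integers(0, mode_assign.size, size=n_dup)
            for k, s in enumerate(src):
                ids.append(f"c{c}_d{k:04d}")
                rows.append(originals[s].copy())
                labels.append(c)
                modes.append(int(mode_assign[s]))
    dataset = LabeledDataset(
        sample_ids=ids,
        payload=np.stack(rows),
        labels=np.asarray(labels),
        class_names=[f"class{c}" for c in range(spec.n_classes)],
        payload_kind="feature",
    )
    return dataset, np.asarray(modes)


# -- image fixture --------------------------------------------------------


def _motif_mask(shape: str, h: int, w: int, oy: int, ox: int, size: int) -> np.ndarray:
    """Boolean motif mask of the given shape anchored at (oy, ox)."""
    mask = np.zeros((h, w), dtype=bool)
    y0, y1 = oy, min(oy + size, h)
    x0, x1 = ox, min(ox + size, w)
    if shape == "square":
        mask[y0:y1, x0:x1] = True
    elif shape == "cross":
        cy, cx = (y0 + y1) // 2, (x0 + x1) // 2
        mask[y0:y1, max(cx - 1, 0) : cx + 1] = True
        mask[max(cy - 1, 0) : cy + 1, x0:x1] = True
    elif shape == "hstripes":
        mask[y0:y1:2, x0:x1] = True
    elif shape == "vstripes":
        mask[y0:y1, x0:x1:2] = True
    elif shape == "diamond":
        cy, cx = (y0 + y1) / 2 - 0.5, (x0 + x1) / 2 - 0.5
        yy, xx = np.mgrid[0:h, 0:w]
        mask[(np.abs(yy - cy) + np.abs(xx - cx)) <= size / 2] = True
    elif shape == "frame":
        mask[y0:y1, x0:x1] = True
        if y1 - y0 > 2 and x1 - x0 > 2:
            mask[y0 + 1 : y1 - 1, x0 + 1 : x1 - 1] = False
    else:  # pragma: no cover
        raise ValueError(f"unknown motif {shape!r}")
    return mask


def _scheme_table(
    spec: FixtureSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-(class, mode) motif colours and background levels.

    Visible modes draw colours and backgrounds from the interior of the
    intensity range; the last ``hidden_modes_per_class`` modes of every
    class draw at least one colour channel and the background from the
    extremes, outside the visible palette's channel span.  This gives the
    hidden sub-modes ground-truth novelty in the sense the range judgment
    measures: their appearance lies outside the region of intensity space
    the visible modes occupy, not merely at a distant point within it.
    """
    n_vis = spec.modes_per_class - spec.hidden_modes_per_class
    n_hid = spec.hidden_modes_per_class
    min_sep = 0.25  # L1 distance between any two motif colours
    accepted: list[np.ndarray] = []

    def draw(sampler) -> np.ndarray:
        for _ in range(2000):
            cand = sampler()
            if all(np.abs(cand - a).sum() >= min_sep for a in accepted):
                accepted.append(cand)
                return cand
        raise RuntimeError("could not draw separated colour schemes")

    def extreme_colour() -> np.ndarray:
        lo = rng.uniform(0.0, 0.08, size=3)
        hi = rng.uniform(0.92, 1.0, size=3)
        return np.where(rng.integers(0, 2, size=3), hi, lo)

    colours = np.empty((spec.n_classes, spec.modes_per_class, 3))
    backgrounds = np.empty((spec.n_classes, spec.modes_per_class))
    for c in range(spec.n_classes):
        for m in range(n_vis):
            colours[c, m] = draw(lambda: rng.uniform(0.2, 0.8, size=3))
            backgrounds[c, m] = rng.uniform(0.25, 0.75)
        for m in range(n_vis, spec.modes_per_class):
            colours[c, m] = draw(extreme_colour)
            backgrounds[c, m] = (
                rng.uniform(0.92, 1.0) if rng.integers(0, 2) else rng.uniform(0.0, 0.08)
            )
    return colours, backgrounds


def _render(
    spec: FixtureSpec,
    colours: np.ndarray,
    backgrounds: np.ndarray,
    c: int,
    m: int,
    index: int,
) -> np.ndarray:
    """Render one instance; deterministic in (seed, class, mode, index)."""
    h, w = spec.image_shape
    rng = np.random.default_rng([spec.seed, c, m, index])
    size = max(4, min(h, w) // 2)
    oy = int(rng.integers(0, h - size + 1))
    ox = int(rng.integers(0, w - size + 1))
    img = np.full((h, w, 3), backgrounds[c, m], dtype=np.float64)
    mask = _motif_mask(_MOTIFS[c % len(_MOTIFS)], h, w, oy, ox, size)
    img[mask] = colours[c, m]
    # pixel noise scaled so noise_scale ~ 0.5 gives mild speckle
    img += rng.normal(0.0, 0.04 * spec.noise_scale, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_image_fixture(
    spec: FixtureSpec,
) -> tuple[LabeledDataset, np.ndarray]:
    """Procedurally drawn image dataset plus per-sample mode labels.

    Class -> shape motif; (class, mode) -> colour scheme; instance -> motif
    position and pixel noise.  Duplicates are exact pixel copies.
    """
    if spec.level != "image":
        raise ValueError("spec.level must be 'image'")
    h, w = spec.image_shape
    if min(h, w) < 8:
        raise ValueError(f"image_shape {spec.image_shape} too small for motifs")
    rng = np.random.default_rng(spec.seed)
    colours, backgrounds = _scheme_table(spec, rng)
    ids: list[str] = []
    imgs: list[np.ndarray] = []
    labels: list[int] = []
    modes: list[int] = []
    n_dup = _n_duplicates(spec)
    for c in range(spec.n_classes):
        mode_assign = _assign_modes(spec)
        originals = [
            _render(spec, colours, backgrounds, c, int(m), i)
            for i, m in enumerate(mode_assign)
        ]
        for i, (img, m) in enumerate(zip(originals, mode_assign)):
            ids.append(f"c{c}_s{i:04d}")
            imgs.append(img)
            labels.append(c)
            modes.append(int(m))
        if n_dup:
            src = rng.integers(0, mode_assign.size, size=n_dup)
            for k, s in enumerate(src):
                ids.append(f"c{c}_d{k:04d}")
                imgs.append(originals[s].copy())
                labels.append(c)
                modes.append(int(mode_assign[s]))
    dataset = LabeledDataset(
        sample_ids=ids,
        payload=np.stack(imgs),
        labels=np.asarray(labels),
        class_names=[f"class{c}" for c in range(spec.n_classes)],
        payload_kind="image",
    )
    return dataset, np.asarray(modes)


def generate_fixture(spec: FixtureSpec) -> tuple[LabeledDataset, np.ndarray]:
    """Dispatch on ``spec.level``."""
    if spec.level == "feature":
        return generate_feature_fixture(spec)
    return generate_image_fixture(spec)


def make_base_pool_with_hidden_modes(
    fixture: LabeledDataset,
    mode_labels: Sequence[int],
    spec: FixtureSpec,
    split: SplitSpec | None = None,
) -> tuple[LabeledDataset, LabeledDataset, LabeledDataset, dict[str, int]]:
    """Two-stage split where the base avoids hidden modes.

    Train/test uses ``split.train_fraction`` (default 0.8) over all modes;
    the base then receives ``floor(base_fraction_of_train * n)`` samples per
    class drawn only from the non-hidden modes
    ``0 .. modes_per_class - hidden_modes_per_class - 1``; the last
    ``hidden_modes_per_class`` modes appear exclusively in pool and test.
    Returns (base, pool, test, id -> mode map).
    """
    mode_labels = np.asarray(mode_labels)
    if mode_labels.shape[0] != len(fixture):
        raise ValueError("mode_labels length != fixture size")
    split = split or SplitSpec(seed=spec.seed)
    mode_of = dict(zip(fixture.sample_ids, (int(m) for m in mode_labels)))
    train, test = stratified_split(fixture, split)
    hidden = set(
        range(spec.modes_per_class - spec.hidden_modes_per_class, spec.modes_per_class)
    )
    rng = np.random.default_rng(split.seed + 2)
    base_ids: list[str] = []
    pool_ids: list[str] = []
    for c in range(train.n_classes):
        cls_ids = [
            s for s, lbl in zip(train.sample_ids, train.labels) if lbl == c
        ]
        n_base = int(np.floor(split.base_fraction_of_train * len(cls_ids)))
        eligible = [s for s in cls_ids if mode_of[s] not in hidden]
        if n_base == 0:
            raise ValueError(
                f"base fraction {split.base_fraction_of_train} yields zero base "
                f"samples for class {train.class_names[c]!r}"
            )
        if len(eligible) < n_base:
            raise ValueError(
                f"class {train.class_names[c]!r} has only {len(eligible)} "
                f"non-hidden samples but the base needs {n_base}"
            )
        chosen = set(
            np.asarray(eligible, dtype=object)[
                rng.permutation(len(eligible))[:n_base]
            ]
        )
        base_ids.extend(s for s in cls_ids if s in chosen)
        pool_ids.extend(s for s in cls_ids if s not in chosen)
    return train.subset(base_ids), train.subset(pool_ids), test, mode_of
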