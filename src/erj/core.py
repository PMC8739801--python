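"""Embedding-range judgment (ERJ): the information-value score and ranking.

The base set's embeddings occupy, per dimension, the interval
``[min_j, max_j]`` — the *embedding range*.  A pool sample's information
value is the number of dimensions falling strictly outside that range
(its out-of-range *count*), with the summed distance to the nearer bound
(*exceedance*) as a secondary magnitude signal.  Boundary-equal values are
inside, so every sample used to fit a range scores zero against it.

Ranking strategies:

``hard_first``
    descending count — most novel samples first (suits deeper extractors).
``easy_first``
    ascending count among samples with count >= 1; zero-count samples are
    appended last.  Mildly novel samples first (suits shallow extractors).
``bad_data``
    ascending count with zero-count (fully in-range, redundant) samples
    first — used to select deliberately redundant data for contrast.
``random``
    seeded permutation baseline.

Ties are broken by descending exceedance, then lexicographic sample id, so
every ranking is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .extractor import EmbeddingMatrix

STRATEGIES = ("hard_first", "easy_first", "bad_data", "random")


@dataclass
class EmbeddingRange:
    """Per-dimension [lower, upper] bounds spanned by a fitted embedding set."""

    lower: np.ndarray
    upper: np.ndarray
    n_fit: int

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=np.float64)
        self.upper = np.asarray(self.upper, dtype=np.float64)
        if self.lower.shape != self.upper.shape or self.lower.ndim != 1:
            raise ValueError("lower/upper must be 1-D vectors of equal length")
        if np.any(self.lower > self.upper):
            raise ValueError("lower bound exceeds upper bound")

    @property
    def dim(self) -> int:
        return int(self.lower.shape[0])

    def contains(self, other: "EmbeddingRange") -> bool:
        """True if ``other``'s interval is inside this one, every dimension."""
        return bool(
            np.all(self.lower <= other.lower) and np.all(self.upper >= other.upper)
        )


@dataclass
class OutOfRangeProfile:
    """Out-of-range dimension count and total exceedance for one sample."""

    sample_id: str
    count: int
    exceedance: float


@dataclass
class SelectionConfig:
    strategy: str = "hard_first"
    per_class_quota: int = 40
    class_balanced: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(
                f"unknown strategy {self.strategy!r}; choose from {STRATEGIES}"
            )
        if self.per_class_quota < 1:
            raise ValueError("per_class_quota must be >= 1")


def fit_range(base_embeddings: EmbeddingMatrix) -> EmbeddingRange:
    """Exact per-dimension min/max over the base embeddings (all classes pooled)."""
    values = base_embeddings.values
    if values.shape[0] == 0:
        raise ValueError("cannot fit a range on an empty embedding matrix")
    if not np.all(np.isfinite(values)):
        raise ValueError("embedding matrix contains non-finite values")
    return EmbeddingRange(
        lower=values.min(axis=0), upper=values.max(axis=0), n_fit=values.shape[0]
    )


def fit_ranges_by_class(
    embeddings: EmbeddingMatrix, labels: Sequence[int]
) -> dict[int, EmbeddingRange]:
    """Per-class variant: one range per class label (non-default option)."""
    labels = np.asarray(labels)
    if labels.shape[0] != len(embeddings):
        raise ValueError("labels length != embedding rows")
    ranges: dict[int, EmbeddingRange] = {}
    for c in np.unique(labels):
        rows = np.flatnonzero(labels == c)
        sub = EmbeddingMatrix(
            sample_ids=[embeddings.sample_ids[i] for i in rows],
            values=embeddings.values[rows],
        )
        ranges[int(c)] = fit_range(sub)
    return ranges


def judge(
    erange: EmbeddingRange, pool_embeddings: EmbeddingMatrix
) -> list[OutOfRangeProfile]:
    """Score each pool sample against the range, preserving row order.

    ``count`` is the number of dimensions with ``x < lower`` or ``x > upper``
    (strict; boundary values are inside); ``exceedance`` sums the distances
    to the violated bounds.
    """
    values = pool_embeddings.values
    if values.shape[1] != erange.dim:
        raise ValueError(
            f"dimension mismatch: pool has {values.shape[1]}, range has {erange.dim}"
        )
    below = erange.lower - values  # positive where under the lower bound
    above = values - erange.upper  # positive where over the upper bound
    out = (below > 0) | (above > 0)
    counts = out.sum(axis=1)
    exceed = np.where(below > 0, below, 0.0).sum(axis=1) + np.where(
        above > 0, above, 0.0
    ).sum(axis=1)
    return [
        OutOfRangeProfile(sample_id=sid, count=int(c), exceedance=float(e))
        for sid, c, e in zip(pool_embeddings.sample_ids, counts, exceed)
    ]


def rank_pool(
    profiles: Sequence[OutOfRangeProfile], config: SelectionConfig
) -> list[str]:
    """Order sample ids by information value under the configured strategy."""
    if not profiles:
        raise ValueError("no profiles to rank")
    # tie-break: larger exceedance first, then lexicographic id
    def tie(p: OutOfRangeProfile) -> tuple:
        return (-p.exceedance, p.sample_id)

    if config.strategy == "hard_first":
        ordered = sorted(profiles, key=lambda p: (-p.count,) + tie(p))
    elif config.strategy == "bad_data":
        ordered = sorted(profiles, key=lambda p: (p.count,) + tie(p))
    elif config.strategy == "easy_first":
        nonzero = sorted(
            (p for p in profiles if p.count > 0), key=lambda p: (p.count,) + tie(p)
        )
        zero = sorted((p for p in profiles if p.count == 0), key=tie)
        ordered = nonzero + zero
    elif config.strategy == "random":
        rng = np.random.default_rng(config.seed)
        ordered = list(profiles)
        perm = rng.permutation(len(ordered))
        ordered = [ordered[i] for i in perm]
    else:  # pragma: no cover - guarded by SelectionConfig
        raise ValueError(f"unknown strategy {config.strategy!r}")
    return [p.sample_id for p in ordered]


@dataclass
class SelectionBatch:
    """One round's selection: chosen ids per class plus any shortfalls."""

    selected: dict[str, list[str]]
    shortfall: dict[str, int] = field(default_factory=dict)

    @property
    def ids(self) -> list[str]:
        return [sid for ids in self.selected.values() for sid in ids]


def select_batch(
    ranked_per_class: Mapping[str, Sequence[str]], config: SelectionConfig
) -> SelectionBatch:
    """Take the top ``per_class_quota`` ids from each class ranking.

    If a class's pool holds fewer candidates than the quota, all remaining
    candidates are taken and the shortfall is reported per class.
    """
    quota = config.per_class_quota
    selected: dict[str, list[str]] = {}
    shortfall: dict[str, int] = {}
    for cls, ranking in ranked_per_class.items():
        take = list(ranking[:quota])
        selected[cls] = take
        if len(take) < quota:
            shortfall[cls] = quota - len(take)
    return SelectionBatch(selected=selected, shortfall=shortfall)


def profiles_to_frame(
    profiles: Sequence[OutOfRangeProfile], labels: Mapping[str, int] | None = None
) -> pd.DataFrame:
    """Tabulate profiles (sample_id, [label,] count, exceedance)."""
    df = pd.DataFrame(
        {
            "sample_id": [p.sample_id for p in profiles],
            "count": [p.count for p in profiles],
            "exceedance": [p.exceedance for p in profiles],
        }
    )
    if labels is not None:
        df.insert(1, "label", [labels[p.sample_id] for p in profiles])
    return df


def save_profiles(
    profiles: Sequence[OutOfRangeProfile],
    path: str | Path,
    labels: Mapping[str, int] | None = None,
) -> None:
    """Export profiles as delimited text."""
    sep = "\t" if Path(path).suffix == ".tsv" else ","
    profiles_to_frame(profiles, labels).to_csv(path, sep=sep, index=False)
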