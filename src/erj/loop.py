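"""The iterated select-and-retrain loop.

Each round: fine-tune the extractor on the current base data, evaluate on
the fixed test set, then (unless stopping) embed base and pool, fit the
embedding range on the base, judge every pool sample, rank per class under
the configured strategy and move the top ``round_budget`` samples per class
from pool to base.  The loop stops when the round budget is exhausted
(``rounds_max``), the pool is empty, or test accuracy reaches
``target_accuracy``.

The range is refitted on the *entire* current base every round and pool
samples are judged with the *current* round's extractor, so a sample's
information value changes as the base grows.  Per-round seeds are derived
from the master seed and recorded, making a full run replayable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .core import (
    SelectionConfig,
    fit_range,
    fit_ranges_by_class,
    judge,
    rank_pool,
    select_batch,
)
from .data_model import LabeledDataset
from .extractor import Extractor, ExtractorSpec, build_extractor, embed, finetune


@dataclass
class LoopConfig:
    rounds_max: int = 6
    round_budget: int = 40  # per-class quota per round
    target_accuracy: float | None = None
    strategy: str = "hard_first"
    retrain_mode: str = "warm"
    epochs_per_round: int = 20
    learning_rate: float = 0.01
    batch_size: int = 32
    per_class_range: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rounds_max < 1:
            raise ValueError("rounds_max must be >= 1")
        if self.target_accuracy is not None and not (0 < self.target_accuracy <= 1):
            raise ValueError("target_accuracy must be in (0, 1]")
        if self.retrain_mode not in ("warm", "cold"):
            raise ValueError("retrain_mode must be 'warm' or 'cold'")


@dataclass
class SelectionRound:
    """Record of one loop iteration."""

    round_index: int
    selected_ids: list[str]
    base_size_after: dict[str, int]
    test_accuracy: float
    shortfall: dict[str, int]
    seeds_used: dict[str, int]
    stopped: str | None = None  # reason the loop ended at this round, if any

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


def evaluate(
    handle: Extractor, test: LabeledDataset
) -> tuple[float, np.ndarray]:
    """Top-1 accuracy and confusion matrix on the test set."""
    if len(test) == 0:
        raise ValueError("test dataset is empty")
    if test.labels.max() >= handle.spec.head_classes:
        raise ValueError("test labels outside the head's class vocabulary")
    pred = handle.predict(test)
    cm = _sk_confusion(
        test.labels, pred, labels=np.arange(handle.spec.head_classes)
    )
    return float(np.trace(cm) / cm.sum()), cm


def _round_seed(master: int, round_index: int) -> int:
    # stable, bounded sub-seed per round
    return int((master * 1_000_003 + round_index) % (2**31 - 1))


def _check_disjoint(*named: tuple[str, LabeledDataset]) -> None:
    for i in range(len(named)):
        for j in range(i + 1, len(named)):
            (na, a), (nb, b) = named[i], named[j]
            overlap = set(a.sample_ids) & set(b.sample_ids)
            if overlap:
                raise ValueError(
                    f"{na} and {nb} share sample ids: {sorted(overlap)[:10]}"
                )


def run_loop(
    base: LabeledDataset,
    pool: LabeledDataset,
    test: LabeledDataset,
    extractor_spec: ExtractorSpec,
    config: LoopConfig,
) -> list[SelectionRound]:
    """Run the full selection loop; returns one record per executed round."""
    _check_disjoint(("base", base), ("pool", pool), ("test", test))
    if len(pool) == 0:
        raise ValueError("pool is empty at the start of the loop")
    if base.class_names != pool.class_names or base.class_names != test.class_names:
        raise ValueError("base/pool/test class vocabularies differ")

    handle = build_extractor(extractor_spec)
    rounds: list[SelectionRound] = []
    sel_cfg = SelectionConfig(
        strategy=config.strategy,
        per_class_quota=config.round_budget,
        seed=config.seed,
    )
    for r in range(1, config.rounds_max + 1):
        seed_r = _round_seed(config.seed, r)
        if config.retrain_mode == "cold" and r > 1:
            handle = build_extractor(extractor_spec)
        finetune(
            handle,
            base,
            epochs=config.epochs_per_round,
            seed=seed_r,
            lr=config.learning_rate,
            batch_size=config.batch_size,
        )
        accuracy, _ = evaluate(handle, test)

        stopped = None
        if config.target_accuracy is not None and accuracy >= config.target_accuracy:
            stopped = "target_accuracy"
        elif len(pool) == 0:
            stopped = "pool_exhausted"

        selected_ids: list[str] = []
        shortfall: dict[str, int] = {}
        if stopped is None:
            base_emb = embed(handle, base)
            pool_emb = embed(handle, pool)
            if config.per_class_range:
                ranges = fit_ranges_by_class(base_emb, base.labels)
                profiles = []
                for i, sid in enumerate(pool_emb.sample_ids):
                    c = int(pool.labels[i])
                    sub = type(pool_emb)(
                        sample_ids=[sid], values=pool_emb.values[i : i + 1]
                    )
                    profiles.extend(judge(ranges[c], sub))
            else:
                erange = fit_range(base_emb)
                profiles = judge(erange, pool_emb)
            by_class: dict[str, list] = {c: [] for c in pool.class_names}
            for prof, lbl in zip(profiles, pool.labels):
                by_class[pool.class_names[int(lbl)]].append(prof)
            sel_round = SelectionConfig(
                strategy=config.strategy,
                per_class_quota=config.round_budget,
                seed=_round_seed(sel_cfg.seed, 10_000 + r),
            )
            ranked = {
                c: rank_pool(profs, sel_round)
                for c, profs in by_class.items()
                if profs
            }
            batch = select_batch(ranked, sel_round)
            selected_ids = batch.ids
            shortfall = batch.shortfall
            base = base.concat(pool.subset(selected_ids))
            remaining = [s for s in pool.sample_ids if s not in set(selected_ids)]
            pool = pool.subset(remaining)
            if r == config.rounds_max:
                stopped = "rounds_max"

        rounds.append(
            SelectionRound(
                round_index=r,
                selected_ids=selected_ids,
                base_size_after=base.class_counts(),
                test_accuracy=accuracy,
                shortfall=shortfall,
                seeds_used={"train": seed_r, "master": config.seed},
                stopped=stopped,
            )
        )
        if stopped is not None:
            break
        # if the pool just emptied, the next round trains on the full base,
        # evaluates, and records the pool_exhausted stop
    return rounds


def save_round_log(rounds: list[SelectionRound], path: str | Path) -> None:
    """Serialize the round log as JSON lines (one SelectionRound per line)."""
    Path(path).write_text("\n".join(r.to_json() for r in rounds) + "\n")


def load_round_log(path: str | Path) -> list[SelectionRound]:
    rounds = []
    for line in Path(path).read_text().splitlines():
        if line.strip():
            rounds.append(SelectionRound(**json.loads(line)))
    return rounds


def replay_base_membership(
    base: LabeledDataset, rounds: list[SelectionRound]
) -> list[list[str]]:
    """Base id membership after each round, reconstructed from the log."""
    current = list(base.sample_ids)
    history = []
    for r in rounds:
        current = current + list(r.selected_ids)
        history.append(list(current))
    return history
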