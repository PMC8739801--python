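"""Experiment harness: learning curves, strategy contrasts, mode recovery.

Three experiment families, all desk-scale:

* ``accuracy_vs_quantity`` — test accuracy as a function of cumulative
  selected data, per strategy and extractor depth, against the all-data
  reference trained with the same protocol.
* ``good_vs_bad`` — paired curves for the most-novel-first (``hard_first``)
  and fully-in-range (``bad_data``) selections at identical budgets and
  seeds, so differences are attributable to selection alone.
* ``novel_mode_recovery`` — the mechanism check: what fraction of round-1
  selections carry hidden-mode ground truth, versus the random expectation.

Accuracy at round ``r`` is measured after fine-tuning on the base as it
stood entering the round, i.e. it reflects the data selected in rounds
``1 .. r-1``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .core import SelectionConfig, fit_range, judge, rank_pool, select_batch
from .data_model import LabeledDataset
from .extractor import EmbeddingMatrix, ExtractorSpec, build_extractor, embed
from .loop import LoopConfig, SelectionRound, evaluate, run_loop
from .extractor import finetune


@dataclass
class CurvePoint:
    """One (budget, accuracy) point of a learning curve."""

    fraction_of_train: float
    n_samples_per_class: float
    mean_accuracy: float
    accuracy_per_seed: list[float]
    strategy: str
    depth_preset: str

    def __post_init__(self) -> None:
        for a in self.accuracy_per_seed:
            if not (0.0 <= a <= 1.0):
                raise ValueError("accuracy outside [0, 1]")


def _train_size_per_class(base: LabeledDataset, pool: LabeledDataset) -> float:
    total = len(base) + len(pool)
    return total / base.n_classes


def _reference_accuracy(
    base: LabeledDataset,
    pool: LabeledDataset,
    test: LabeledDataset,
    extractor_spec: ExtractorSpec,
    config: LoopConfig,
    n_rounds: int,
    seed: int,
) -> float:
    """All-data accuracy under the loop's own training protocol.

    Warm loops accumulate epochs across rounds, so the reference trains one
    model for the same cumulative schedule; cold loops retrain from scratch
    each round, so the reference is a fresh model trained for one round's
    epochs.
    """
    full = base.concat(pool)
    spec = replace(extractor_spec, seed=seed)
    handle = build_extractor(spec)
    reference_rounds = 1 if config.retrain_mode == "cold" else n_rounds
    for r in range(1, reference_rounds + 1):
        finetune(
            handle,
            full,
            epochs=config.epochs_per_round,
            seed=(seed * 1_000_003 + r) % (2**31 - 1),
            lr=config.learning_rate,
            batch_size=config.batch_size,
        )
    acc, _ = evaluate(handle, test)
    return acc


def _curve_from_rounds(
    rounds_per_seed: list[list[SelectionRound]],
    base: LabeledDataset,
    pool: LabeledDataset,
    strategy: str,
    depth_preset: str,
) -> list[CurvePoint]:
    """Aggregate per-seed round logs into curve points at shared budgets."""
    train_pc = _train_size_per_class(base, pool)
    base_pc = len(base) / base.n_classes
    n_rounds = min(len(r) for r in rounds_per_seed)
    points = []
    for i in range(n_rounds):
        accs = [rs[i].test_accuracy for rs in rounds_per_seed]
        # accuracy at round i+1 reflects the base entering that round,
        # i.e. the size recorded after round i
        if i == 0:
            n_pc = base_pc
        else:
            sizes = rounds_per_seed[0][i - 1].base_size_after
            n_pc = float(np.mean(list(sizes.values())))
        points.append(
            CurvePoint(
                fraction_of_train=n_pc / train_pc,
                n_samples_per_class=n_pc,
                mean_accuracy=float(np.mean(accs)),
                accuracy_per_seed=[float(a) for a in accs],
                strategy=strategy,
                depth_preset=depth_preset,
            )
        )
    return points


def accuracy_vs_quantity(
    base: LabeledDataset,
    pool: LabeledDataset,
    test: LabeledDataset,
    extractor_spec: ExtractorSpec,
    config: LoopConfig,
    n_seeds: int = 3,
    include_reference: bool = True,
) -> tuple[list[CurvePoint], float | None]:
    """Learning curve for one (strategy, depth), meaned over seeds.

    Returns (points, all-data reference accuracy meaned over the same seeds,
    or None if ``include_reference`` is false).
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    rounds_per_seed = []
    ref_accs = []
    for s in range(n_seeds):
        seed = config.seed + 7919 * s
        cfg = replace(config, seed=seed)
        spec = replace(extractor_spec, seed=seed)
        rounds_per_seed.append(run_loop(base, pool, test, spec, cfg))
        if include_reference:
            ref_accs.append(
                _reference_accuracy(
                    base, pool, test, extractor_spec, config,
                    n_rounds=len(rounds_per_seed[-1]), seed=seed,
                )
            )
    points = _curve_from_rounds(
        rounds_per_seed, base, pool, config.strategy, extractor_spec.depth_preset
    )
    reference = float(np.mean(ref_accs)) if include_reference else None
    return points, reference


def good_vs_bad(
    base: LabeledDataset,
    pool: LabeledDataset,
    test: LabeledDataset,
    extractor_spec: ExtractorSpec,
    config: LoopConfig,
    n_seeds: int = 10,
) -> pd.DataFrame:
    """Paired good-data vs. bad-data curves at identical budgets and seeds.

    "Good" selects the samples with the most out-of-range dimensions
    (``hard_first``); "bad" selects fully in-range, redundant samples
    (``bad_data``).  Returns a tidy frame with one row per
    (seed, arm, round) and a ``delta`` column merged per (seed, round).
    """
    records = []
    for s in range(n_seeds):
        seed = config.seed + 7919 * s
        for arm in ("hard_first", "bad_data"):
            cfg = replace(config, seed=seed, strategy=arm)
            spec = replace(extractor_spec, seed=seed)
            rounds = run_loop(base, pool, test, spec, cfg)
            for r in rounds:
                records.append(
                    {
                        "seed": seed,
                        "arm": arm,
                        "round": r.round_index,
                        "n_selected_before": (r.round_index - 1)
                        * config.round_budget,
                        "accuracy": r.test_accuracy,
                    }
                )
    return pd.DataFrame.from_records(records)


def good_vs_bad_summary(frame: pd.DataFrame) -> pd.DataFrame:
    """Per-budget paired deltas (good - bad) with a sign-test p value."""
    wide = frame.pivot_table(
        index=["seed", "round"], columns="arm", values="accuracy"
    ).reset_index()
    out = []
    for rnd, grp in wide.groupby("round"):
        delta = grp["hard_first"] - grp["bad_data"]
        n_pos = int((delta > 0).sum())
        n_nonzero = int((delta != 0).sum())
        p = (
            stats.binomtest(n_pos, n_nonzero, 0.5, alternative="greater").pvalue
            if n_nonzero
            else 1.0
        )
        out.append(
            {
                "round": rnd,
                "mean_delta": float(delta.mean()),
                "n_positive": n_pos,
                "n_pairs": len(delta),
                "sign_test_p": float(p),
            }
        )
    return pd.DataFrame(out)


def strategy_comparison(
    base: LabeledDataset,
    pool: LabeledDataset,
    test: LabeledDataset,
    extractor_specs: dict[str, ExtractorSpec],
    config: LoopConfig,
    n_seeds: int = 3,
) -> pd.DataFrame:
    """hard_first vs. easy_first curves for each extractor depth.

    One row per (depth, strategy, round, seed); whether mildly novel or
    maximally novel samples help more depends on the extractor's capacity.
    """
    if len(extractor_specs) < 2:
        raise ValueError("need at least two depth presets to compare")
    records = []
    for depth, spec0 in extractor_specs.items():
        for strategy in ("hard_first", "easy_first"):
            for s in range(n_seeds):
                seed = config.seed + 7919 * s
                cfg = replace(config, seed=seed, strategy=strategy)
                spec = replace(spec0, seed=seed)
                rounds = run_loop(base, pool, test, spec, cfg)
                for r in rounds:
                    records.append(
                        {
                            "depth": depth,
                            "strategy": strategy,
                            "round": r.round_index,
                            "seed": seed,
                            "accuracy": r.test_accuracy,
                        }
                    )
    return pd.DataFrame.from_records(records)


def strategy_summary(frame: pd.DataFrame) -> pd.DataFrame:
    """Per-depth hard_first minus easy_first deltas at first and final round."""
    out = []
    for depth, grp in frame.groupby("depth"):
        wide = grp.pivot_table(
            index=["seed", "round"], columns="strategy", values="accuracy"
        ).reset_index()
        delta = wide["hard_first"] - wide["easy_first"]
        first = wide["round"] == wide["round"].min()
        final = wide["round"] == wide["round"].max()
        out.append(
            {
                "depth": depth,
                "first_round_delta": float(delta[first].mean()),
                "final_round_delta": float(delta[final].mean()),
            }
        )
    return pd.DataFrame(out)


def novel_mode_recovery(
    base: LabeledDataset,
    pool: LabeledDataset,
    mode_of: dict[str, int],
    hidden_modes: set[int],
    strategy: str = "hard_first",
    quota: int = 10,
    seed: int = 0,
    extractor_spec: ExtractorSpec | None = None,
) -> dict[str, float]:
    """Fraction of round-1 selections that carry hidden-mode ground truth.

    Works directly on feature payloads (``payload_kind='feature'``), or runs
    an untrained-embedding pass when ``extractor_spec`` is given for images.
    Returns the selected fraction alongside the random-selection expectation
    (the hidden-mode share of the pool).
    """
    missing = [s for s in pool.sample_ids if s not in mode_of]
    if missing:
        raise ValueError(f"pool ids without mode labels: {missing[:5]}")
    if base.payload_kind == "feature":
        base_emb = EmbeddingMatrix(base.sample_ids, base.payload)
        pool_emb = EmbeddingMatrix(pool.sample_ids, pool.payload)
    else:
        if extractor_spec is None:
            raise ValueError("image payloads need an extractor_spec")
        handle = build_extractor(extractor_spec)
        base_emb = embed(handle, base)
        pool_emb = embed(handle, pool)
    erange = fit_range(base_emb)
    profiles = judge(erange, pool_emb)
    cfg = SelectionConfig(strategy=strategy, per_class_quota=quota, seed=seed)
    by_class: dict[str, list] = {c: [] for c in pool.class_names}
    for prof, lbl in zip(profiles, pool.labels):
        by_class[pool.class_names[int(lbl)]].append(prof)
    ranked = {c: rank_pool(p, cfg) for c, p in by_class.items() if p}
    batch = select_batch(ranked, cfg)
    chosen = batch.ids
    hidden_sel = sum(1 for s in chosen if mode_of[s] in hidden_modes)
    hidden_pool = sum(1 for s in pool.sample_ids if mode_of[s] in hidden_modes)
    return {
        "selected_fraction": hidden_sel / len(chosen) if chosen else 0.0,
        "random_expectation": hidden_pool / len(pool),
        "n_selected": float(len(chosen)),
    }


def curve_frame(points: list[CurvePoint]) -> pd.DataFrame:
    """One row per CurvePoint, for CSV export."""
    return pd.DataFrame(
        [
            {
                "fraction_of_train": p.fraction_of_train,
                "n_samples_per_class": p.n_samples_per_class,
                "mean_accuracy": p.mean_accuracy,
                "strategy": p.strategy,
                "depth_preset": p.depth_preset,
                "accuracy_per_seed": ";".join(f"{a:.4f}" for a in p.accuracy_per_seed),
            }
            for p in points
        ]
    )


def plot_curves(
    frames: dict[str, pd.DataFrame], path: str, reference: float | None = None
) -> None:
    """Accuracy vs. per-class quantity, one line per labeled curve."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, df in frames.items():
        ax.plot(df["n_samples_per_class"], df["mean_accuracy"], marker="o",
                label=label)
    if reference is not None:
        ax.axhline(reference, ls="--", c="gray", label="all data")
    ax.set_xlabel("base samples per class")
    ax.set_ylabel("test accuracy")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
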