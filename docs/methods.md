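# Methods

## The selection model

ERJ treats the training set's embeddings as defining an *occupied region*
of feature space: per dimension, the closed interval between the minimum
and maximum value any base sample attains.  A pool sample's information
value is the number of dimensions in which its embedding falls strictly
outside that region (the out-of-range **count**), with the summed distance
to the violated bounds (**exceedance**) as a secondary magnitude signal.
The model's central assumption is that a sample inside the range in every
dimension is, to the current extractor, a recombination of appearances
already represented — redundant — whereas a sample outside in many
dimensions carries appearances the base set does not cover.

Boundary-equal values count as inside.  This makes range fitting and
judging mutually consistent: every sample used to fit a range scores
exactly zero against it, with no epsilon to tune.  The range is fitted
globally, pooling all classes; a per-class variant (`per_class_range`) is
available but not the default, since the judgment is about coverage of the
feature space, not class geometry.

"Several dimensions outside" is operationalized as a *ranking*, not a
threshold: under a fixed per-class budget K per round, any absolute cutoff
would be redundant.  Four orderings are provided:

- `hard_first` — descending count: most novel first.  Suits extractors with
  the capacity to absorb very new material quickly.
- `easy_first` — ascending count among samples with count ≥ 1, zero-count
  samples last: mildly novel first, a self-paced schedule for
  weaker/shallower extractors.  Zero-count samples are excluded from the
  nonzero prefix because a sample with no out-of-range dimension carries no
  new information by the model's own definition.
- `bad_data` — ascending count with zero-count samples first: deliberately
  redundant selection, used as the contrast arm.
- `random` — seeded permutation baseline.

Ties break by descending exceedance, then lexicographic sample id, so every
ranking is fully deterministic.

## The loop

Each round fine-tunes the extractor on the current base, evaluates on the
fixed test set, then refits the range on the *entire* current base, judges
the pool with the *current* extractor, and moves the top K per class from
pool to base.  Information value is therefore dynamic: as selected samples
enter the base, the range widens and their neighbourhoods stop being novel.
Stale profiles are never reused across rounds.  Stopping: round budget
exhausted, pool empty, or test accuracy at/above `target_accuracy`.
Evaluation happens every round, before that round's selection, so the
accuracy recorded at round r reflects the data selected in rounds 1..r−1.

Per-round training seeds are derived deterministically from the master seed
and recorded in each round's log entry; a run is replayable from
(config, seed) alone, and `provenance.json` stores a hash of base
membership after every round.

## Extractors

The feature extractors are compact convolutional networks written directly
in NumPy (3×3 same-padding convolutions, ReLU, 2×2 max pooling, global
average pooling, dense softmax head; He initialization; Adam).  Pure NumPy
arithmetic plus seeded initialization and shuffling makes training
bit-reproducible on a platform, which the loop's replay guarantees rely
on.  Three presets follow VGG-16 prefixes in depth and relative width —
shallow (4 conv / 1 pool), middle (7 / 2), deep (13 / 4), channel widths
doubling from a configurable base width (default 64, the VGG value) — plus
a `tiny` preset (2 conv / 1 pool, base width 8) sized so a full multi-round
loop runs in minutes on one CPU.

The embedding is the global average pool of the final convolutional
stage's activations, giving a fixed dimension (the final channel count)
independent of image size.  `embed` is pure: it never updates parameters.

Defaults that matter, all overridable in `LoopConfig`:

| parameter | default | why |
| --- | --- | --- |
| learning rate | 0.01 | Adam on few-hundred-sample bases; converges in tens of epochs on the fixtures without diverging |
| epochs_per_round | 20 | enough for the tiny preset to fit a small base |
| batch size | 32 | one to a few batches per epoch at desk scale; the redundancy-sufficiency experiment uses 16 — more update steps per epoch noticeably stabilizes optimization on the smallest bases |
| retrain_mode | warm | continue from the previous round's parameters; `cold` (fresh reinitialization each round) is steadier when each round injects strongly out-of-distribution samples, and the contrast experiments use it |
| round budget K | 40/class | one round = 5% of an 800-per-class training set |
| splits | 8:2 then 1:9 | train/test, then base/pool, stratified per class, floor rounding |

Whether splits should be random or curated is not determined by the
protocol; random stratified with a recorded seed is implemented.  Random
initialization (no pretrained weights) keeps the package download-free and
self-contained.

## Synthetic fixtures

The generators produce the two data situations the method's claims are
about, with ground truth attached.

**Feature level.**  Each class is a Gaussian mixture: `modes_per_class`
centers at pairwise distance ≥ `mode_separation`, isotropic noise
`noise_scale`, and a `duplication_rate` fraction of rows that are exact
copies of earlier rows.  The last `hidden_modes_per_class` modes of each
class are *support-novel*: their centers are pushed outside the visible
centers' span in a few randomly chosen dimensions (by 0.5–1.5 ×
`mode_separation`).  This is deliberate.  An axis-aligned range can only
ever detect novelty that leaves the per-dimension span; a "hidden" mode
sitting inside the visible modes' bounding box — however distant in
Euclidean terms — is invisible to the mechanism by construction, and a
fixture whose ground-truth novelty the instrument cannot express would
test nothing.  Hidden modes model appearance clusters outside the occupied
region, which is the situation the method claims to exploit.

**Image level.**  Small RGB images; the class determines a shape motif
(square, cross, stripes, …), each (class, mode) pair has its own colour
scheme (motif colour + background level), and instances jitter in motif
position with mild pixel noise.  Visible modes draw colours from the
interior of the intensity range ([0.2, 0.8] per channel); hidden modes
draw at least the extremes ([0, 0.08] ∪ [0.92, 1.0]) for colour and
background — the image-level analogue of support-novelty, with the further
property that a network never shown a hidden mode's palette has no basis
to classify it, so hidden-mode test accuracy genuinely depends on whether
selection recovered hidden-mode training samples.  Duplicates are exact
pixel copies.

Everything is byte-reproducible from (spec, seed); per-image generators
are keyed by (seed, class, mode, instance).

**What the fixtures do not model:** natural image statistics, intra-class
continuous variation, label noise, class imbalance, or near-duplicates
beyond exact copies (a jittered-duplicate option exists at feature level
via small `noise_scale`).  Passing on these fixtures shows the selection
mechanism works when redundancy and novelty exist and are expressible in
the embedding; it does not predict effect sizes on natural datasets.

## Study conditions for the behavioural checks

All behavioural checks run the tiny preset on 16×16 images or 16-d feature
fixtures, 3 classes, sized so each check completes in minutes on one CPU:

- **Novel-mode recovery** — feature fixture, 4 modes/class with 1 hidden,
  separation 3.0 = 6 × noise (0.5), 50 samples/class, quota 5/class,
  20 seeds.  Measured: median fraction of round-1 hard-first selections
  carrying hidden-mode ground truth vs. the hidden share of the pool
  (random expectation).  The null control regenerates the fixture with
  *no* support-novel mode (all modes ordinary and base-eligible) and
  checks the last mode is not preferentially selected.
- **Good vs. bad data** — image fixture, 100 samples/class, 1 hidden mode,
  duplication 0.3; arms `hard_first` vs. `bad_data` at identical budgets
  (8/class/round, 3 rounds) and identical seeds; cold retraining, 80
  epochs/round.  Measured: per-budget paired accuracy deltas and a sign
  test.
- **Redundancy sufficiency** — image fixture with duplication 0.5 and no
  hidden modes; warm loop (40 epochs/round, batch 16, quota 16/class,
  4 rounds) against an all-data reference trained with the same cumulative
  schedule.  Measured: the smallest training fraction whose mean accuracy
  is within 0.02 of the reference.  (For a cold loop the matched reference
  is instead a fresh model trained for one round's epochs, since cold
  rounds do not accumulate training.)

`scripts/acceptance.py` recomputes these with seeds derived from `--seed`
(fixture geometry for the image experiments is part of the fixed study
conditions; training/selection stochasticity follows the seed).

## Numerical choices and degenerate inputs

- Strict inequalities define "outside"; a single-sample range is the
  degenerate interval [x, x] and everything off that point counts.
- Floor rounding in splits, remainder to test/pool; a fraction that
  floors any class to zero raises.
- Pool exhaustion: a class with fewer candidates than the quota
  contributes all of them, and the shortfall is recorded per class in the
  round log.
- Non-finite embeddings or training losses abort with diagnostics rather
  than propagate.
- 2×2 max-pooling requires even spatial dimensions; input shapes must be
  divisible by 2^(pool layers).

## Known limitations

- The axis-aligned range ignores correlations between dimensions: novelty
  expressed only jointly (inside every marginal interval but outside the
  joint support) scores zero.  This is inherent to the method, and the
  fixtures are constructed so ground-truth novelty is marginal, not joint.
- The range is an extreme statistic, so a single outlier base sample can
  swallow a whole region of feature space.
- NumPy training is single-threaded-ish and desk-scale; the full-scale
  presets (base width 64, 224×224 inputs) are structurally supported but
  impractical to train on one CPU, and no pretrained weights are shipped.
- With very small bases, warm retraining at the default learning rate can
  oscillate between rounds; the contrast experiments use cold retraining
  for that reason.
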