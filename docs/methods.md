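# Methods

## Model and scope

`swarmlayer` implements a feature-to-feature "intermediate layer" for
two-class embedding classification: a swarm optimizer (MGTO, GTO, PSO or
EHO) run once per sample, with one scalar agent per feature, plus the
surrounding pipeline (stratified splitting, layer training by grid
search, classifier head, metrics). Real feature extraction from images
is out of scope by design; a pluggable adapter interface
(`swarmlayer.extraction.extract`) accepts any callable mapping an image
path to a vector, and the synthetic generator stands in for extraction
everywhere else.

## Population semantics and the iteration loop

One optimizer run transforms one sample's feature vector. Agents are
scalars; the population size is the feature dimension (minimum 5, the
fitness window size); bounds are the sample's own `[min, max]`. Each
iteration applies the exploration update to every agent, recomputes the
local-variance fitness, selects the silverback (maximum fitness, ties to
the lowest index), and then applies the silverback-follow step when
`|C| >= 1` or the competition step otherwise. Positions are clipped to
the bounds after every update — the equations can leave the range, and
clipping is what guarantees the output of the transform stays within the
input's range (the invariant the table-level tests assert). A
`max_iter` of 0 returns the input unchanged.

The fitness of agent `i` is the population variance (divide by 5) of the
five-element window centred on `i`; windows at the edges shift inward so
they always contain five valid values. PSO, which is conventionally a
minimizer, is run in the same maximize-the-variance orientation as the
other three layers; its personal bests replace on strict improvement.
EHO runs as a single clan, and its "worst" agent (lowest variance
fitness) is resampled from `xmin + (xmax − xmin + 1)·rand` before
clipping.

## Randomness and determinism

All draws flow through a `RandomStream` (PCG64). Per iteration the
shared coefficients are drawn once, in the order r4 (for `F`), `l`, `Z`,
r5 (for `Q`), the `E`-branch selector and the `E` draw; per agent-update
the stream supplies the branch selector, the branch randoms r1/r2/r3 and
the random-partner index, in the order the symbols appear in the
governing equation. `N1` is uniform on the position bounds; `N2` is a
standard normal rejection-truncated to `[0, 1]`.

Row `i` of a table is transformed with a stream seeded by
`(layer_seed, i)`, so transforming any subset of rows (passing their
original indices) reproduces the corresponding rows of a full-table
transform — useful for incremental work and asserted by tests.
`ScriptedStream` replays a fixed value sequence for pinned-draw checks.

## Parameter conventions where the update equations are underdetermined

Several constants admit more than one reading; the package fixes them as
follows and exposes flags where both readings are defensible:

* `M`, the silverback-follow magnitude, is `(|mean(X)|^g)^(1/g)` with
  `g = 2^L` (`g_mode="pow2"`, default) or `g = 2L` (`"linear"`); a zero
  population mean defines `M = 0` since the power chain is singular for
  non-integer exponents. For scalar agents the pow2 form collapses
  algebraically to `|mean(X)|` whenever the mean is non-zero.
* `l` is continuous uniform on `[−1, 1]` (`l_mode="continuous"`,
  default) or integer-valued in `{−1, 0, 1}` (`"integer"`).
* Exploration branch selection uses a single uniform draw per agent:
  `rand < p` jumps to a random position, else `rand >= 0.5` moves toward
  a partner, else takes the difference (GTO) or sine–cosine (MGTO) step.
  The three conditions are not mutually exclusive as printed; this
  ordering is the original GTO's.
* The MGTO third exploration branch is evaluated as
  `X − L·rad·sin(X − Xr) + rad·cos(X − Xr)`: the minimal reading that
  balances the parentheses and keeps the sine–cosine pairing.
* The sine–cosine radius decays as `rad = const − t·(const/max_iter)`
  with `const = 3`, the customary initial amplitude of sine–cosine
  searches.

## Tunable parameters

| parameter | meaning | default |
|---|---|---|
| `p` | probability of the jump-to-random exploration branch | 0.3 |
| `beta` | scales the competition step via `A = β·E` | 0.7 |
| `max_iter` | iterations per sample (also the `rad`/`C` decay horizon) | 11 |
| `const` | initial sine–cosine radius (MGTO only) | 3 |
| `w, c1, c2` | PSO inertia / cognitive / social weights | 0.6, 0.7, 0.9 |
| `alpha, beta_e` | EHO attraction toward and scaling of the clan centre | 0.9, 0.8 |

The defaults are the ideal values reported for MobileNetV3 embeddings of
the largest dataset; they are starting points, not universal optima —
the intended workflow is to re-fit them per dataset with `fit_layer`.

## Layer training

`fit_layer` is a two-stage search: sweep `max_iter` (default 1..20) with
every continuous axis at 0.5, then sweep the continuous axes (default
0.0..1.0 in steps of 0.1) at the winning `max_iter`; a `joint=True` flag
evaluates the full product grid instead. The head is retrained from
scratch at every point with the same head seed, so surface differences
reflect only the transform. The recorded accuracy surface contains grid
members only (stage-1 midpoint probes are internal scaffolding unless
0.5 is itself on an axis), which keeps two contracted properties exact:
the winner is an element of the requested grid, and its recorded
accuracy equals both the surface maximum and an independent
re-evaluation from scratch. Ties break toward smaller `max_iter`, then
smaller axis values in declaration order.

## Classifier head

The head is batch normalization (momentum 0.99, epsilon 0.001) → dense
256 with ReLU, L2 kernel regularizer 0.016, L1 activity and bias
regularizers 0.006 → dropout 0.45 → dense 2 with softmax, trained with
Adamax (lr 0.001, batch 128, up to 100 epochs) on sparse categorical
cross-entropy, early stopping on validation loss (patience 5, minimum
delta 0, best weights restored) and learning-rate reduction on plateau
(factor 0.2, patience 4). It is implemented directly in numpy — forward,
backward and optimizer are a few dense matrix expressions — which keeps
training bit-reproducible under the config seed (weight init, batch
shuffling and dropout masks share one generator).

Numerical choices: batch-norm running statistics are initialized from
the first training batch rather than from 0/1 — under 0.99 momentum a
cold start would leave a train/inference mismatch that visibly distorts
short trainings (degenerate constant-feature inputs are the clearest
case). The activity regularizer is applied as the per-sample mean of the
L1 norm of the dense activations so its weight is batch-size invariant.
Validation loss includes the regularization penalties, mirroring what
the training loss optimizes. Softmax is computed with max-subtraction;
cross-entropy clips probabilities at 1e−12.

Metrics treat label 1 (the carcinoma analog) as positive. Scores with a
zero denominator are reported as 0 and flagged in `Metrics.undefined`;
rendered tables round to two decimals while JSON retains full precision.

## Splitting

`stratified_split` shuffles within each class and takes
`floor(0.15·n)` validation and test rows, remainder to training. This
floor convention reproduces eleven of the twelve published per-class
split counts exactly; the 439-sample class is the single exception
(published 307/66/66, floor yields 309/65/65 — no uniform rounding rule
reproduces all twelve rows), and the tests assert it as a known
exception rather than papering over it.

## Synthetic embeddings: what they do and do not show

The generator draws class-0 rows i.i.d. `N(0, σ²)` per feature and
shifts the mean of a contiguous leading block (fraction
`shifted_fraction`, default one half) by `mean_shift·σ` for class 1;
`relu_clip` optionally maps features through `max(0, ·)` to mimic the
non-negativity and sparsity of real CNN embeddings. Fixtures exist at
the exact per-class totals of the three public datasets (2494/2698,
89/439, 201/495).

Passing tests on these tables establish that the update mathematics,
seeding, splitting, training protocol and orchestration behave as
specified. They do **not** establish that the swarm layer improves
accuracy on real embeddings: with independent Gaussian features the
transform — which is label-free, per-sample, and injects
uniform-in-range jumps during exploration — removes linear class signal,
and the end-to-end acceptance run accordingly shows a *negative*
accuracy change versus the no-layer baseline (about −33% at seed 1). On
features where the baseline is already strong, the published evaluation
itself reports negative increases for the PSO, EHO and GTO layers; any
gain on real data must come from embedding structure (sparsity,
correlated blocks, class-dependent ranges) that the i.i.d. generator
deliberately does not model. The acceptance therefore targets the
mathematics and the worked-example statistics, not the
dataset-dependent headline accuracies.

## Problem sizes

Default verification sizes were chosen to exercise every code path at
comfortable desk scale: equation oracles use populations of 5–10 agents
and at most 3 iterations; transform invariants run 100 randomized
vectors per algorithm; head sanity checks use 2000 samples at 32
dimensions; the grid-search oracle uses a 200×16 table with a 3×3×2
grid and a 6-epoch head; the acceptance pipeline uses a 300×16 table
with a 6×5×5 grid and a 40-epoch head.

## Known limitations

* Agents are scalars; the vector-agent (multi-dimensional) formulation
  of these optimizers is not implemented.
* The transform's effect on accuracy is data-dependent and frequently
  negative; the package reports it rather than promising it.
* The head is a faithful but compact implementation of the stated
  training protocol; framework-specific numerical details (e.g. exact
  regularizer batch scaling elsewhere) may differ at the margin.
* No class weighting: imbalanced tables are trained with plain
  cross-entropy, matching the stated protocol.
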