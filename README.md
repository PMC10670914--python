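# swarmlayer

Swarm-intelligence feature-transform layers for two-class image-embedding
classification pipelines.

## The problem

Histopathological diagnosis of oral squamous cell carcinoma (OSCC) from
microscope images is commonly automated with transfer learning: a frozen
CNN backbone (MobileNetV3, EfficientNetB3, InceptionV2) turns each image
into a 1280- or 1536-dimensional embedding, and a small trainable head
classifies the embedding as Normal or OSCC. `swarmlayer` implements an
*intermediate layer* for such pipelines: a population-based optimizer —
the Modified Gorilla Troops Optimizer (MGTO), with plain GTO, particle
swarm optimization (PSO) and elephant herding optimization (EHO) as
baselines — that re-maps each embedding, feature by feature, before the
head sees it. The package is for researchers who want to study this
family of feature transforms and for anyone needing a clean, fully
deterministic reference implementation of the update equations.

## The method

One optimizer run transforms one sample. Its `N` features become `N`
scalar agents `X_1..X_N` confined to the sample's own range
`[Ll, Ul] = [min X, max X]`. Each iteration applies:

1. **Exploration** — with probability `p` an agent jumps to
   `(Ul − Ll)·r1 + Ll`; otherwise it moves toward a random partner
   `Xr` via `(r2 − C)·Xr + L·H`, or (MGTO) takes the sine–cosine step
   `X − L·rad·sin(X − Xr) + rad·cos(X − Xr)`,
   where `C = (cos(2 r4) + 1)(1 − t/T)`, `L = C·l`, `H = Z·X`, with
   `l ~ U[−1, 1]`, `Z ~ U[−C, C]`.
2. **Silverback selection** — the agent with the highest fitness
   `F(X_i) = Var(X_{i−2}, …, X_{i+2})` (population variance of the
   five-element index window, shifted inward at the edges) leads.
3. **Follow or compete** — if `|C| ≥ 1`, agents follow the silverback
   (`L·M·rad·sin(X − X_sb) + X` in MGTO); otherwise they compete
   (`X_sb − rad·cos(X_sb·Q − X·Q)·A` with `Q = 2 r5 − 1`, `A = β·E`).

The sine–cosine amplitude `rad = const·(1 − t/T)` decays linearly from
`const = 3` to 0. After `T = max_iter` iterations the final positions are
the transformed features: same length, same order, always inside the
input's range.

"Training" the layer is a two-stage grid search on downstream validation
accuracy: sweep `max_iter` with `p = β = 0.5`, then sweep `(p, β)` at the
winning `max_iter`. The downstream head (batch norm → 256-unit ReLU dense
with L2 kernel 0.016 and L1 activity/bias 0.006 → dropout 0.45 → 2-unit
softmax; Adamax, early stopping on validation loss, learning-rate
reduction on plateau) is retrained from scratch at every grid point.

Because the real histopathology image sets and pretrained backbones are
external, the package ships a synthetic embedding generator (two-class
Gaussian tables with a block mean shift, at the exact per-class sample
counts of the three public datasets) so every stage is testable offline.

## Worked example

```python
from swarmlayer import (HeadConfig, SplitSpec, SynthSpec, confusion_and_metrics,
                        generate_two_class_features, predict, stratified_split,
                        train_head)

table = generate_two_class_features(
    SynthSpec(n_class0=600, n_class1=600, dim=32, mean_shift=2.0, seed=1))
splits = stratified_split(table, SplitSpec(seed=0))
head = train_head(splits.train, splits.val, HeadConfig(seed=0))
labels, _ = predict(head, splits.test)
print(confusion_and_metrics(splits.test.labels, labels).to_dict())
```

prints (see `examples/03_train_classifier_head.py`):

```
split sizes: train=840 val=180 test=180
test confusion: tp=90 fp=0 fn=0 tn=90
{'tp': 90, 'fp': 0, 'fn': 0, 'tn': 90, 'accuracy': 1.0, 'precision': 1.0,
 'recall': 1.0, 'f1': 1.0}
```

A 2σ class gap on half of 32 features is linearly separable, so the head
classifies the held-out test split perfectly; precision/recall/F1 refer
to the positive (OSCC-analog) class. The `examples/` directory walks
through each capability: single-vector transforms, synthetic tables and
scatter averages, head training, layer grid search, and the full
pipeline with its baseline comparison. A thin CLI mirrors the stages
(`swarmlayer synth | split | fit-layer | transform | fit-head |
evaluate | run`).

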