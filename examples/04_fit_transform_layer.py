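"""Train the MGTO layer's hyperparameters by grid search.

Stage 1 sweeps the iteration budget with p and beta held at 0.5; stage 2
sweeps (p, beta) at the stage-1 winner.  Every grid point retrains the
head from scratch on the transformed training set and scores the
transformed validation set.
"""

from swarmlayer import (
    GridSpec,
    HeadConfig,
    SplitSpec,
    SynthSpec,
    fit_layer,
    generate_two_class_features,
    stratified_split,
)

table = generate_two_class_features(
    SynthSpec(n_class0=100, n_class1=100, dim=16, mean_shift=1.5, seed=13)
)
splits = stratified_split(table, SplitSpec(seed=0))

grid = GridSpec(max_iter_values=[1, 3, 5],
                axes={"p": [0.1, 0.5, 0.9], "beta": [0.3, 0.7]})
fit = fit_layer(splits.train, splits.val, HeadConfig(epochs=8, seed=0),
                grid, "mgto", seed=0)

print("accuracy surface (max_iter, p, beta -> validation accuracy):")
for key, acc in sorted(fit.accuracy_surface.items()):
    print(f"  max_iter={key[0]:<2} p={key[1]:.1f} beta={key[2]:.1f} -> {acc:.3f}")

best = fit.best_params.params
print(f"\nbest point: max_iter={best.max_iter}, p={best.p}, beta={best.beta} "
      f"(validation accuracy {fit.best_validation_accuracy:.3f})")
print("The fitted layer JSON round-trips losslessly:")
print(fit.to_json()[:120] + "...")
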