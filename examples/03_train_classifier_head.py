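"""Split a table 70:15:15 and train the classifier head.

The head is batch normalization, a 256-unit regularized ReLU layer,
dropout 0.45 and a 2-unit softmax, trained with Adamax and early
stopping on validation loss.
"""

from swarmlayer import (
    HeadConfig,
    SplitSpec,
    SynthSpec,
    confusion_and_metrics,
    generate_two_class_features,
    predict,
    render_metrics_table,
    stratified_split,
    train_head,
)

table = generate_two_class_features(
    SynthSpec(n_class0=600, n_class1=600, dim=32, mean_shift=2.0, seed=1)
)
splits = stratified_split(table, SplitSpec(seed=0))
print(f"split sizes: train={splits.train.n_samples} "
      f"val={splits.val.n_samples} test={splits.test.n_samples}")

head = train_head(splits.train, splits.val, HeadConfig(seed=0))
last = head.training_log[-1]
print(f"trained {len(head.training_log)} epochs "
      f"(early stopping monitors validation loss); "
      f"final val accuracy {last['val_accuracy']:.3f}")

labels, _ = predict(head, splits.test)
metrics = confusion_and_metrics(splits.test.labels, labels)
print(f"test confusion: tp={metrics.tp} fp={metrics.fp} "
      f"fn={metrics.fn} tn={metrics.tn}")
print(render_metrics_table([("synthetic-32d", "NO", metrics)]))
print("Precision/recall/F1 describe identification of the positive "
      "(carcinoma-analog) class; accuracy covers both classes.")
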