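"""Consensus pseudo-labelling with two branches and a feature-fusion head.

Trains a grayscale CNN branch and an RGB transfer branch on a small labelled
phantom pool, lets them vote on pseudo-labels for the unlabelled pool
(disagreements rejected), and finishes with a fusion classifier whose input
is the concatenation of the two branch feature vectors.  Prints the ledger
of each voting iteration and the fused model's test accuracy.
"""

from pseudofuse import (
    LabeledDataset,
    PhantomConfig,
    RunConfig,
    ThresholdSchedule,
    TrainConfig,
    generate_phantoms,
    run_ssl,
    stratified_split,
)

train = generate_phantoms(PhantomConfig(per_class_count=25, image_size=32, seed=0))
test = generate_phantoms(PhantomConfig(per_class_count=10, image_size=32, seed=10_000))
test = LabeledDataset(tuple(f"test/{s}" for s in test.sample_ids),
                      test.images, test.labels, 4)
split = stratified_split(train, labelled_fraction=0.4, seed=0)
print(f"{len(split.labelled)} labelled / {len(split.unlabelled)} unlabelled "
      f"/ {len(test)} test images")

config = RunConfig(
    mode="ssl_consensus_fusion",
    labelled_fraction=0.4,
    schedule=ThresholdSchedule((0.8, 0.6)),  # relaxed for this tiny demo
    train=TrainConfig(epochs=50, batch_size=8, learning_rate=1e-3, seed=0,
                      lr_callback=None),
    epochs_per_ssl_iteration=10,
    validation_fraction=0.0,
    tiny=True,
    seed=0,
)
report = run_ssl(split, test, config)
for row in report.ledger.rows:
    print(f"iteration {row.iteration}: tau={row.threshold}, "
          f"accepted {row.accepted}, rejected {row.rejected}")
print(f"pseudo-label precision: {report.pseudo_label_precision}")
print(f"fused-model test accuracy: {report.test_accuracy:.2f}")
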