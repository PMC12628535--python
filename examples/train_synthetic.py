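"""Train the dual-branch contrastive model on planted-motif data.

Generates a small balanced dataset whose positives carry a GGACU motif at
the window centre, trains the full model (contrastive + supervised) and
prints held-out metrics.  Runs in about a minute on one CPU.
"""

import numpy as np

from methylcl import (
    RunConfig,
    SyntheticConfig,
    TrainConfig,
    full_report,
    generate_dataset,
    prepare_features,
    run_experiment,
    score_records,
)

data_cfg = SyntheticConfig(n_pos=160, n_neg=160, motif="GGACU", seed=7)
train_records, test_records = generate_dataset(data_cfg)
print(f"{len(train_records)} train / {len(test_records)} test records")

run_cfg = RunConfig(
    k=3,
    seed=0,
    model=dict(conv_filters=16, hidden=16, proj_dim=16),
    training=TrainConfig(epochs=10, batch_size=16, seed=0),
)
model, history = run_experiment(train_records, test_records, run_cfg)
print(f"trained {len(history)} epochs; "
      f"final val acc {history[-1]['val_acc']:.3f}, lambda {history[-1]['lambda']}")

scores = score_records(model, test_records, run_cfg)
_, _, labels = prepare_features(test_records, run_cfg.k, run_cfg.target_len)
for name, value in full_report(scores, labels).items():
    print(f"{name:>6}: {value:.4f}")
# AUROC near 1 shows the planted motif is recovered; with insertion_prob=0
# in SyntheticConfig the same pipeline stays near 0.5 (no signal to learn).
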