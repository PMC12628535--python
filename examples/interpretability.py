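"""Position- and feature-level interpretability of a trained model.

Trains a small model on planted-motif data, then asks (1) which window
positions the prediction is sensitive to, by input gradients and by base
substitution, and (2) which dimensions of the fused representation separate
the classes, by Welch t-statistics.
"""

import numpy as np

from methylcl import (
    RunConfig,
    SyntheticConfig,
    TrainConfig,
    feature_t_stats,
    generate_dataset,
    gradient_importance,
    perturbation_importance,
    prepare_features,
    run_experiment,
)
from methylcl.autodiff import Tensor
from methylcl.evaluation import top_features

data_cfg = SyntheticConfig(n_pos=120, n_neg=120, motif="GGACU", seed=3)
train_records, test_records = generate_dataset(data_cfg)
run_cfg = RunConfig(
    k=3, seed=0,
    model=dict(conv_filters=16, hidden=16, proj_dim=16),
    training=TrainConfig(epochs=10, batch_size=16, seed=0),
)
model, _ = run_experiment(train_records, test_records, run_cfg)

grad = gradient_importance(model, test_records[:12], run_cfg)
pert = perturbation_importance(model, test_records[:12], run_cfg)
print("motif occupies positions 20-24 (window centre)")
print("gradient importance, motif vs background mean: "
      f"{grad[20:25].mean():.4f} vs {np.concatenate([grad[:15], grad[30:]]).mean():.4f}")
print("top-3 positions by perturbation importance:",
      [int(i) for i in np.argsort(-pert)[:3]])

# class separation in the fused 256-dim representation h
ids, cgr, labels = prepare_features(test_records, run_cfg.k, run_cfg.target_len)
H = np.vstack([
    model.encode((model.embedding(ids[i : i + 16]), Tensor(cgr[i : i + 16]))).h.data
    for i in range(0, len(labels), 16)
])
t = feature_t_stats(H, labels)
print("top-5 discriminative representation dimensions (index, t):")
for idx, val in top_features(t, k=5):
    print(f"  dim {idx:3d}  t = {val:+.2f}")
# Large |t| marks dimensions whose distribution differs between modified and
# unmodified windows; a trained model concentrates signal in a few of them.
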