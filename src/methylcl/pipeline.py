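"""End-to-end experiment plumbing: records -> features -> trained model.

This is the layer the CLI and the evaluation utilities sit on.  A RunConfig
bundles every knob (k-mer size, embedding backend, architecture, augmentation
and training hyper-parameters) and is fully serialisable, so any run can be
reproduced from the resolved-config file written beside its outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from . import sequence_io
from .augmentation import AugmentationConfig, GRID_ETA, GRID_P_MASK
from .cgr import encode_batch
from .embedding import make_backend, select_kmer_variant
from .network import Model, ModelConfig, uses_contrastive, variant_config
from .sequence_io import SequenceRecord, build_vocab, kmerize, pad_sequence
from .training import TrainConfig, predict_proba, train


@dataclass
class RunConfig:
    k: int = 6
    backend: str = "lookup"
    embed_dim: int | None = None  # None -> backend default (32 lookup / 768 pretrained)
    target_len: int = sequence_io.DEFAULT_LENGTH
    variant: str = "s_cba_bil"
    model: dict = field(default_factory=dict)  # ModelConfig overrides
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    model_dir: str | None = None  # pretrained weights location
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "augmentation" in d and isinstance(d["augmentation"], dict):
            d["augmentation"] = AugmentationConfig(**d["augmentation"])
        if "training" in d and isinstance(d["training"], dict):
            tr = dict(d["training"])
            if isinstance(tr.get("augmentation"), dict):
                tr["augmentation"] = AugmentationConfig(**tr["augmentation"])
            d["training"] = TrainConfig(**tr)
        return cls(**d)


def prepare_features(
    records: list[SequenceRecord], k: int, target_len: int = sequence_io.DEFAULT_LENGTH
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pad, tokenize and CGR-encode records into (ids, cgr_states, labels)."""
    vocab = build_vocab(k)
    padded = [
        SequenceRecord(r.id, pad_sequence(r.seq, target_len), r.label) for r in records
    ]
    ids = np.array([kmerize(r.seq, k, vocab).ids for r in padded], dtype=np.int64)
    cgr = encode_batch(padded)
    labels = np.array([r.label for r in padded], dtype=np.int64)
    return ids, cgr, labels


def build_model(config: RunConfig) -> Model:
    """Instantiate the variant's architecture with its embedding backend."""
    backend_cfg = select_kmer_variant(config.k, config.backend, config.embed_dim)
    rng = np.random.default_rng(config.seed)
    embedding = make_backend(backend_cfg, rng=rng, model_dir=config.model_dir)
    mc = variant_config(
        config.variant,
        embed_dim=backend_cfg.dim,
        seed=config.seed,
        **config.model,
    )
    return Model(mc, embedding=embedding)


def _resolved_training(config: RunConfig) -> TrainConfig:
    tc = replace(config.training, augmentation=config.augmentation)
    if not uses_contrastive(config.variant):
        tc = replace(tc, use_contrastive=False)
    return tc


def run_experiment(
    train_records: list[SequenceRecord],
    val_records: list[SequenceRecord],
    config: RunConfig,
) -> tuple[Model, list[dict]]:
    """Build, train and return the model plus its training history."""
    model = build_model(config)
    tr = prepare_features(train_records, config.k, config.target_len)
    va = prepare_features(val_records, config.k, config.target_len)
    tc = _resolved_training(config)
    tc = replace(tc, seed=config.seed)
    return train(model, tr, va, tc)


def score_records(
    model: Model, records: list[SequenceRecord], config: RunConfig
) -> np.ndarray:
    """Positive-class probability per record, eval mode."""
    ids, cgr, _ = prepare_features(records, config.k, config.target_len)
    return predict_proba(model, ids, cgr, config.training.batch_size)


def grid_search_augmentation(
    train_records: list[SequenceRecord],
    val_records: list[SequenceRecord],
    config: RunConfig,
    p_mask_grid: tuple = GRID_P_MASK,
    eta_grid: tuple = GRID_ETA,
) -> list[dict]:
    """Evaluate the augmentation grid by validation AUROC; argmax flagged.

    Returns one row per (p_mask, eta) with the trained model's validation
    AUROC, mirroring the hyper-parameter search that selected the default
    p_mask = 0.15, eta = 0.01.
    """
    from .evaluation import auroc

    _, _, y_va = prepare_features(val_records, config.k, config.target_len)
    rows = []
    for p_mask in p_mask_grid:
        for eta in eta_grid:
            cfg = replace(
                config, augmentation=AugmentationConfig(p_mask=p_mask, eta=eta)
            )
            model, _ = run_experiment(train_records, val_records, cfg)
            scores = score_records(model, val_records, cfg)
            rows.append({"p_mask": p_mask, "eta": eta, "val_auroc": auroc(scores, y_va)})
    best = max(range(len(rows)), key=lambda i: rows[i]["val_auroc"])
    for i, row in enumerate(rows):
        row["best"] = i == best
    return rows


def save_run_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(config.to_dict(), fh, indent=2)


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(json.load(fh))
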