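"""Multi-task training loop: contrastive + supervised objectives.

Each optimisation step embeds the batch, runs one clean forward pass for the
classification loss and — when the contrastive term is enabled — two
independently augmented forward passes whose projections feed the NT-Xent
loss.  The weighted sum L_cls + lambda * L_cont is minimised with Adam under
a warm-up/decay learning-rate schedule; validation accuracy drives both the
adaptive lambda and early stopping (patience 15, best checkpoint restored).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .augmentation import AugmentationConfig, sample_mask
from .autodiff import Tensor, concat
from .network import Model
from .objectives import (
    ContrastiveBatch,
    TrainingState,
    cross_entropy_loss,
    lr_schedule,
    ntxent_batch_loss,
    total_loss,
    update_lambda,
)


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 32
    base_lr: float = 1e-3
    patience: int = 15
    tau: float = 0.5
    use_contrastive: bool = True
    cls_input: str = "clean"  # "clean" | "augmented"
    two_stage: bool = False  # contrastive pre-train then supervised fine-tune
    pretrain_epochs: int = 10  # only used when two_stage
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    seed: int = 0


class Adam:
    def __init__(self, params: list[Tensor], beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def _interleave(zq: Tensor, zk: Tensor) -> Tensor:
    """Stack query/key projections as rows (2i, 2i+1) of one matrix."""
    B = zq.shape[0]
    order = np.empty(2 * B, dtype=int)
    order[0::2] = np.arange(B)
    order[1::2] = B + np.arange(B)
    return concat([zq, zk], axis=0)[order]


def _accuracy(model: Model, ids, cgr, labels, batch_size: int) -> float:
    preds = predict_proba(model, ids, cgr, batch_size)
    return float(np.mean((preds >= 0.5).astype(int) == labels))


def predict_proba(model: Model, ids, cgr, batch_size: int = 64) -> np.ndarray:
    """Positive-class probabilities in eval mode."""
    out = []
    for lo in range(0, ids.shape[0], batch_size):
        sl = slice(lo, lo + batch_size)
        X = model.embedding(ids[sl])
        probs = model.forward_probs((X, Tensor(cgr[sl])), train_mode=False)
        out.append(probs.data[:, 1])
    return np.concatenate(out) if out else np.empty(0)


def train(
    model: Model,
    train_data: tuple,
    val_data: tuple,
    config: TrainConfig,
) -> tuple[Model, list[dict]]:
    """Optimise `model`; returns it with best-validation weights restored.

    `train_data` / `val_data` are (ids, cgr_states, labels) arrays as built
    by `pipeline.prepare_features`.  History rows record per-epoch losses,
    lambda, learning rate and validation accuracy.
    """
    ids_tr, cgr_tr, y_tr = train_data
    ids_va, cgr_va, y_va = val_data
    if ids_tr.shape[0] == 0 or ids_va.shape[0] == 0:
        raise ValueError("training and validation sets must be non-empty")

    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters)
    state = TrainingState()
    best_state = model.state_copy()
    history: list[dict] = []
    n = ids_tr.shape[0]
    aug = config.augmentation

    for epoch in range(config.epochs):
        state.epoch = epoch
        lr = lr_schedule(epoch, config.base_lr)
        if config.two_stage:
            stage_cont = epoch < config.pretrain_epochs and config.use_contrastive
            stage_cls = not stage_cont
        else:
            stage_cont = config.use_contrastive
            stage_cls = True

        perm = rng.permutation(n)
        ep_total = ep_cls = ep_cont = 0.0
        n_batches = 0
        for lo in range(0, n, config.batch_size):
            idx = perm[lo : lo + config.batch_size]
            if idx.size < 2:
                continue  # NT-Xent needs at least one pair of samples
            ids_b, cgr_b, y_b = ids_tr[idx], cgr_tr[idx], y_tr[idx]
            X = model.embedding(ids_b)
            cgr_t = Tensor(cgr_b)

            cls_loss = Tensor(0.0)
            cont_loss = Tensor(0.0)
            views = []
            if stage_cont:
                for _ in range(2):
                    M = sample_mask(X.shape, aug.p_mask, rng)
                    noise = rng.standard_normal(cgr_b.shape) * aug.eta
                    Xv = X * Tensor(M)
                    cv = Tensor(cgr_b + noise)
                    enc = model.encode((Xv, cv), train_mode=True, rng=rng)
                    z = model.project(enc.h, train_mode=True, rng=rng).z
                    views.append((enc, z))
                Z = _interleave(views[0][1], views[1][1])
                cont_loss = ntxent_batch_loss(ContrastiveBatch(Z, tau=config.tau))
            if stage_cls:
                if config.cls_input == "augmented" and views:
                    probs = [
                        model.classify(enc.h, train_mode=True, rng=rng).probs
                        for enc, _ in views
                    ]
                    cls_loss = (
                        cross_entropy_loss(probs[0], y_b)
                        + cross_entropy_loss(probs[1], y_b)
                    ) * 0.5
                else:
                    enc = model.encode((X, cgr_t), train_mode=True, rng=rng)
                    probs = model.classify(enc.h, train_mode=True, rng=rng).probs
                    cls_loss = cross_entropy_loss(probs, y_b)

            loss = total_loss(cls_loss, cont_loss, state.lam)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss.data!r} "
                    f"(cls={cls_loss.data!r}, cont={cont_loss.data!r})"
                )
            opt.zero_grad()
            loss.backward()
            opt.step(lr)
            ep_total += float(loss.data)
            ep_cls += float(cls_loss.data)
            ep_cont += float(cont_loss.data)
            n_batches += 1

        val_acc = _accuracy(model, ids_va, cgr_va, y_va, config.batch_size)
        state.val_acc_history.append(val_acc)
        history.append(
            {
                "epoch": epoch,
                "lr": lr,
                "lambda": state.lam,
                "train_loss": ep_total / max(n_batches, 1),
                "cls_loss": ep_cls / max(n_batches, 1),
                "cont_loss": ep_cont / max(n_batches, 1),
                "val_acc": val_acc,
            }
        )

        if val_acc > state.best_val_acc:
            state.best_val_acc = val_acc
            state.best_epoch = epoch
            best_state = model.state_copy()
            state.patience_counter = 0
        else:
            state.patience_counter += 1
            if state.patience_counter >= config.patience:
                break
        update_lambda(state)

    model.load_state(best_state)
    return model, history


def write_history_csv(history: list[dict], path: str | Path) -> None:
    cols = ["epoch", "lr", "lambda", "train_loss", "cls_loss", "cont_loss", "val_acc"]
    with open(path, "w") as fh:
        fh.write(",".join(cols) + "\n")
        for row in history:
            fh.write(",".join(f"{row[c]:.10g}" for c in cols) + "\n")
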