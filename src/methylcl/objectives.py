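"""Losses and schedules for multi-task contrastive training.

The contrastive term is the NT-Xent loss of SimCLR: for a mini-batch of N
samples the augmentation stage yields 2N views, laid out so that rows
(2k, 2k+1) (0-based) are the two views of sample k.  For a positive pair
(q, k),

    l_qk = -log  exp(sim(z_q, z_k)/tau) / sum_{j != q} exp(sim(z_q, z_j)/tau)

with cosine similarity sim and temperature tau (default 0.5); the batch loss
averages both directed terms over all N pairs.  The supervised term is
categorical cross-entropy; the total objective is

    L_total = L_cls + lambda * L_cont

where lambda starts at 0.5, stays fixed for the first 10 epochs, and is then
nudged by 0.05 toward [0.3, 0.5] bounds according to the sign of the
least-squares slope of validation accuracy over a 5-epoch sliding window
(falling accuracy shrinks the contrastive weight, rising accuracy restores
it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor

CE_EPS = 1e-12
LAMBDA_MIN = 0.3
LAMBDA_MAX = 0.5
LAMBDA_STEP = 0.05
LAMBDA_FREEZE_EPOCHS = 10
LAMBDA_WINDOW = 5
DEFAULT_TAU = 0.5


@dataclass
class ContrastiveBatch:
    """2N projection rows with views of sample k at rows 2k and 2k+1."""

    Z: Tensor  # (2N, P)
    tau: float = DEFAULT_TAU

    def __post_init__(self):
        if not isinstance(self.Z, Tensor):
            self.Z = Tensor(self.Z)
        if self.Z.shape[0] % 2 != 0:
            raise ValueError("contrastive batch must hold an even number of views")
        if self.tau <= 0:
            raise ValueError(f"temperature must be positive, got {self.tau}")

    @property
    def n_pairs(self) -> int:
        return self.Z.shape[0] // 2


def cosine_similarity(u, v) -> float:
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(u @ v / (nu * nv))


def _sim_matrix(batch: ContrastiveBatch) -> Tensor:
    Z = batch.Z
    norms = (Z * Z).sum(axis=1, keepdims=True).clip_min(1e-30) ** 0.5
    Zn = Z / norms
    return (Zn @ Zn.T) * (1.0 / batch.tau)


def _directed_losses(batch: ContrastiveBatch) -> Tensor:
    """Vector of the 2N directed pair losses l_{q, partner(q)}."""
    M = batch.Z.shape[0]
    sims = _sim_matrix(batch)
    # self-similarity is excluded from every denominator
    neg_inf = np.zeros((M, M))
    np.fill_diagonal(neg_inf, -1e30)
    sims = sims + neg_inf
    shift = sims.data.max(axis=1, keepdims=True)
    log_denom = ((sims - shift).exp().sum(axis=1, keepdims=True)).log() + shift
    partner = np.arange(M) ^ 1  # 2k <-> 2k+1
    P = np.zeros((M, M))
    P[np.arange(M), partner] = 1.0
    pos = (sims * P).sum(axis=1, keepdims=True)
    return (log_denom - pos).reshape(M)


def ntxent_pair_loss(batch: ContrastiveBatch, q: int, k: int) -> Tensor:
    """Directed NT-Xent loss for positive pair (q -> k)."""
    M = batch.Z.shape[0]
    if not (0 <= q < M and 0 <= k < M) or (q ^ 1) != k:
        raise IndexError(f"({q}, {k}) is not a positive pair in a batch of {M} views")
    return _directed_losses(batch)[q]

def ntxent_batch_loss(batch: ContrastiveBatch) -> Tensor:
    """Mean of the 2N directed pair losses (both directions of each pair)."""
    return _directed_losses(batch).mean()


def cross_entropy_loss(probs: Tensor, labels: np.ndarray) -> Tensor:
    """Categorical cross-entropy against one-hot (or integer) labels.

    Probabilities of the true class are clamped at 1e-12 before the log.
    """
    if not isinstance(probs, Tensor):
        probs = Tensor(probs)
    labels = np.asarray(labels)
    if labels.ndim == 1:
        onehot = np.zeros(probs.shape)
        onehot[np.arange(labels.size), labels.astype(int)] = 1.0
    else:
        onehot = labels.astype(np.float64)
    return -(Tensor(onehot) * probs.clip_min(CE_EPS).log()).sum(axis=1).mean()


def total_loss(cls_loss, cont_loss, lam: float):
    """L_total = L_cls + lambda * L_cont with lambda in [0.3, 0.5]."""
    if not LAMBDA_MIN <= lam <= LAMBDA_MAX:
        raise ValueError(f"lambda must lie in [{LAMBDA_MIN}, {LAMBDA_MAX}], got {lam}")
    return cls_loss + cont_loss * lam


@dataclass
class TrainingState:
    """Adaptive-weight bookkeeping carried across epochs."""

    lam: float = LAMBDA_MAX
    epoch: int = 0
    val_acc_history: list = field(default_factory=list)
    patience_counter: int = 0
    best_val_acc: float = -np.inf
    best_epoch: int = -1


def update_lambda(state: TrainingState) -> TrainingState:
    """Adjust lambda by the validation-accuracy trend (after the freeze).

    Trend = sign of the least-squares slope over the last 5 recorded epochs;
    negative shrinks lambda by 0.05 (floor 0.3), positive grows it (cap 0.5).
    """
    if state.epoch < LAMBDA_FREEZE_EPOCHS or len(state.val_acc_history) < LAMBDA_WINDOW:
        return state
    window = np.asarray(state.val_acc_history[-LAMBDA_WINDOW:])
    x = np.arange(LAMBDA_WINDOW)
    slope = np.polyfit(x, window, 1)[0]
    if slope < 0:
        state.lam = max(state.lam - LAMBDA_STEP, LAMBDA_MIN)
    elif slope > 0:
        state.lam = min(state.lam + LAMBDA_STEP, LAMBDA_MAX)
    return state


def lr_schedule(epoch: int, base_lr: float) -> float:
    """5-epoch linear warm-up to base_lr, then exponential decay at 0.9/epoch."""
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    if epoch < 5:
        return base_lr * (epoch + 1) / 5.0
    return base_lr * 0.9 ** (epoch - 4)
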