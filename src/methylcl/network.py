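"""Dual-branch encoder, projection head and classification head.

Branch 1 (primary view) runs the embedded token matrix through a cascade of
1-D convolution (ReLU, batch norm, dropout 0.3), a 64-unit bidirectional
LSTM (group norm with 4 groups, dropout 0.3) and tanh attention pooling to a
single context vector c (dimension 128).  Branch 2 (auxiliary view) runs the
CGR state matrix through its own 64-unit BiLSTM and summarises it by
concatenating the two directions' final states (dimension 128).  The fused
representation h = [c ; branch-2 summary] (256) feeds

* a projection head g: one-hidden-layer MLP (dropout 0.1) to a
  low-dimensional z used only by the contrastive loss during training, and
* a classification head: dense 256 -> 128 -> 64 -> 2 with ReLU and dropout
  0.1, softmax output.

Ablation switches reproduce the single-branch and reduced-cascade variants
(CNN, CNN+BiLSTM, CBA, CBA+BiL and their contrastive counterparts).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat, matmul
from .layers import BatchNorm1d, BiLSTM, Conv1dLayer, Dense, GroupNorm, dropout

BRANCH1_MODES = ("cnn", "cnn_bilstm", "cba")


@dataclass
class ModelConfig:
    embed_dim: int = 32
    conv_filters: int = 64
    conv_kernel: int = 3
    hidden: int = 64  # BiLSTM units per direction, both branches
    proj_dim: int = 64  # P, dimension of z
    conv_dropout: float = 0.3
    lstm_dropout: float = 0.3
    head_dropout: float = 0.1
    gn_groups: int = 4
    branch1_mode: str = "cba"
    use_branch1: bool = True
    use_branch2: bool = True
    branch2_summary: str = "final"  # "final" | "mean"
    seed: int = 0

    def __post_init__(self):
        if self.branch1_mode not in BRANCH1_MODES:
            raise ValueError(f"branch1_mode must be one of {BRANCH1_MODES}")
        if not (self.use_branch1 or self.use_branch2):
            raise ValueError("at least one branch must be enabled")


@dataclass(frozen=True)
class EncoderOutput:
    h: Tensor
    attn_weights: np.ndarray | None
    context: Tensor | None
    branch1_seq: Tensor | None


@dataclass(frozen=True)
class ProjectionOutput:
    z: Tensor


@dataclass(frozen=True)
class ClassifierOutput:
    probs: Tensor  # (B, 2) rows summing to 1


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - x.data.max(axis=axis, keepdims=True)  # constant shift
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def attention_pool_scores(H: Tensor, e: Tensor) -> tuple[Tensor, Tensor]:
    """Softmax-normalise scores e over time and pool H with the weights.

    H: (B, T, C); e: (B, T). Returns (weights (B, T), context (B, C)).
    """
    if H.shape[1] == 0:
        raise ValueError("cannot pool an empty sequence")
    a = softmax(e, axis=1)
    c = (H * a.reshape(a.shape[0], a.shape[1], 1)).sum(axis=1)
    return a, c


def attention_pool(H: Tensor, W_a: Tensor, b_a: Tensor, v_a: Tensor):
    """Tanh-scored attention: e_t = v_a . tanh(h_t W_a + b_a)."""
    B, T, C = H.shape
    scores = matmul(matmul(H.reshape(B * T, C), W_a) + b_a, v_a).reshape(B, T)
    return attention_pool_scores(H, scores)


class Model:
    """The full multi-view network; parameters live on the autodiff tape."""

    def __init__(self, config: ModelConfig, embedding=None):
        self.config = config
        rng = np.random.default_rng(config.seed)
        cfg = config
        self.embedding = embedding
        h2 = 2 * cfg.hidden

        if cfg.use_branch1:
            self.conv = Conv1dLayer(cfg.embed_dim, cfg.conv_filters, cfg.conv_kernel, rng)
            self.bn = BatchNorm1d(cfg.conv_filters)
            if cfg.branch1_mode in ("cnn_bilstm", "cba"):
                self.lstm1 = BiLSTM(cfg.conv_filters, cfg.hidden, rng)
                self.gn = GroupNorm(h2, cfg.gn_groups)
            if cfg.branch1_mode == "cba":
                attn_dim = h2
                self.W_a = Tensor(
                    rng.uniform(-0.1, 0.1, size=(attn_dim, attn_dim)), requires_grad=True
                )
                self.b_a = Tensor(np.zeros(attn_dim), requires_grad=True)
                self.v_a = Tensor(rng.uniform(-0.1, 0.1, size=(attn_dim, 1)), requires_grad=True)
        if cfg.use_branch2:
            self.lstm2 = BiLSTM(1, cfg.hidden, rng)

        b1_dim = {"cnn": cfg.conv_filters, "cnn_bilstm": h2, "cba": h2}[cfg.branch1_mode]
        self.h_dim = (b1_dim if cfg.use_branch1 else 0) + (h2 if cfg.use_branch2 else 0)

        if cfg.proj_dim >= self.h_dim:
            warnings.warn(
                f"projection dim P={cfg.proj_dim} is not smaller than "
                f"dim(h)={self.h_dim}; the projection head is meant to reduce "
                "dimensionality",
                stacklevel=2,
            )
        self.proj_hidden = Dense(self.h_dim, self.h_dim, rng)
        self.proj_out = Dense(self.h_dim, cfg.proj_dim, rng)
        self.cls1 = Dense(self.h_dim, 256, rng)
        self.cls2 = Dense(256, 128, rng)
        self.cls3 = Dense(128, 64, rng)
        self.cls_out = Dense(64, 2, rng)

    # -- parameter plumbing ---------------------------------------------------

    @property
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        if self.embedding is not None:
            params += self.embedding.parameters
        cfg = self.config
        if cfg.use_branch1:
            params += self.conv.parameters + self.bn.parameters
            if cfg.branch1_mode in ("cnn_bilstm", "cba"):
                params += self.lstm1.parameters + self.gn.parameters
            if cfg.branch1_mode == "cba":
                params += [self.W_a, self.b_a, self.v_a]
        if cfg.use_branch2:
            params += self.lstm2.parameters
        for layer in (self.proj_hidden, self.proj_out, self.cls1, self.cls2, self.cls3, self.cls_out):
            params += layer.parameters
        return params

    # -- forward passes -------------------------------------------------------

    def branch1_forward(
        self, X: Tensor, train_mode: bool, rng: np.random.Generator | None = None
    ):
        """Primary-view cascade; returns (per-step sequence or None, context, weights)."""
        if X.ndim != 3:
            raise ValueError(f"expected (batch, tokens, dim) input, got shape {X.shape}")
        if rng is None:
            rng = np.random.default_rng(0)
        cfg = self.config
        y = self.conv(X).relu()
        y = self.bn(y, train_mode)
        y = dropout(y, cfg.conv_dropout, train_mode, rng)
        if cfg.branch1_mode == "cnn":
            return None, y.mean(axis=1), None
        seq = self.lstm1(y)
        seq = self.gn(seq)
        seq = dropout(seq, cfg.lstm_dropout, train_mode, rng)
        if cfg.branch1_mode == "cnn_bilstm":
            return seq, self.lstm1.final_states(seq), None
        a, c = attention_pool(seq, self.W_a, self.b_a, self.v_a)
        return seq, c, a

    def branch2_forward(
        self, X_extra: Tensor, train_mode: bool, rng: np.random.Generator | None = None
    ) -> Tensor:
        if X_extra.ndim != 3 or X_extra.shape[2] != 1:
            raise ValueError(f"expected (batch, L0, 1) input, got shape {X_extra.shape}")
        seq = self.lstm2(X_extra)
        if self.config.branch2_summary == "mean":
            return seq.mean(axis=1)
        return self.lstm2.final_states(seq)

    def encode(
        self,
        sample: tuple,
        train_mode: bool = False,
        rng: np.random.Generator | None = None,
    ) -> EncoderOutput:
        """Fuse branch outputs into h = [context ; branch-2 summary]."""
        X, X_extra = sample
        cfg = self.config
        parts = []
        seq = ctx = None
        attn = None
        if cfg.use_branch1:
            seq, ctx, attn_t = self.branch1_forward(X, train_mode, rng)
            attn = None if attn_t is None else attn_t.data
            parts.append(ctx)
        if cfg.use_branch2:
            parts.append(self.branch2_forward(X_extra, train_mode, rng))
        h = parts[0] if len(parts) == 1 else concat(parts, axis=1)
        return EncoderOutput(h=h, attn_weights=attn, context=ctx, branch1_seq=seq)

    def project(
        self, h: Tensor, train_mode: bool = False, rng: np.random.Generator | None = None
    ) -> ProjectionOutput:
        if rng is None:
            rng = np.random.default_rng(0)
        d = self.config.head_dropout
        z = self.proj_hidden(h).relu()
        z = dropout(z, d, train_mode, rng)
        return ProjectionOutput(z=self.proj_out(z))

    def classify(
        self, h: Tensor, train_mode: bool = False, rng: np.random.Generator | None = None
    ) -> ClassifierOutput:
        if rng is None:
            rng = np.random.default_rng(0)
        d = self.config.head_dropout
        y = dropout(self.cls1(h).relu(), d, train_mode, rng)
        y = dropout(self.cls2(y).relu(), d, train_mode, rng)
        y = dropout(self.cls3(y).relu(), d, train_mode, rng)
        return ClassifierOutput(probs=softmax(self.cls_out(y), axis=1))

    def forward_probs(
        self,
        sample: tuple,
        train_mode: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        enc = self.encode(sample, train_mode, rng)
        return self.classify(enc.h, train_mode, rng).probs

    # -- checkpointing --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Parameter archive (.npz) plus a JSON sidecar with the architecture."""
        path = Path(path)
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters)}
        if self.config.use_branch1:
            arrays["bn_mean"] = self.bn.running_mean
            arrays["bn_var"] = self.bn.running_var
        np.savez(path, **arrays)
        sidecar = path.with_suffix(".json")
        meta = {"config": asdict(self.config)}
        if self.embedding is not None:
            meta["embedding"] = {
                "vocab_size": self.embedding.vocab_size,
                "dim": self.embedding.dim,
            }
        sidecar.write_text(json.dumps(meta, indent=2))

    def load_weights(self, path: str | Path) -> None:
        data = np.load(Path(path))
        for i, p in enumerate(self.parameters):
            arr = data[f"p{i}"]
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"checkpoint parameter {i} has shape {arr.shape}, "
                    f"model expects {p.data.shape}: architecture mismatch"
                )
            p.data = arr
        if self.config.use_branch1:
            self.bn.running_mean = data["bn_mean"]
            self.bn.running_var = data["bn_var"]

    def state_copy(self) -> list[np.ndarray]:
        state = [p.data.copy() for p in self.parameters]
        if self.config.use_branch1:
            state += [self.bn.running_mean.copy(), self.bn.running_var.copy()]
        return state

    def load_state(self, state: list[np.ndarray]) -> None:
        n = len(self.parameters)
        for p, arr in zip(self.parameters, state[:n]):
            p.data = arr.copy()
        if self.config.use_branch1:
            self.bn.running_mean = state[n].copy()
            self.bn.running_var = state[n + 1].copy()


def variant_config(name: str, **overrides) -> ModelConfig:
    """Named ablation variants mirroring the study's model family.

    cnn / cnn_bilstm / cba: branch-1-only cascades (no contrastive term);
    cba_bil: dual branch without contrastive; s_cba, s_bil, s_cba_bil: the
    contrastive-trained counterparts.  The returned config covers the
    architecture; the contrastive on/off switch lives in the training config.
    """
    table = {
        "cnn": dict(use_branch1=True, use_branch2=False, branch1_mode="cnn"),
        "cnn_bilstm": dict(use_branch1=True, use_branch2=False, branch1_mode="cnn_bilstm"),
        "cba": dict(use_branch1=True, use_branch2=False, branch1_mode="cba"),
        "cba_bil": dict(use_branch1=True, use_branch2=True, branch1_mode="cba"),
        "s_cba": dict(use_branch1=True, use_branch2=False, branch1_mode="cba"),
        "s_bil": dict(use_branch1=False, use_branch2=True),
        "s_cba_bil": dict(use_branch1=True, use_branch2=True, branch1_mode="cba"),
    }
    if name not in table:
        raise ValueError(f"unknown variant {name!r}; choose from {sorted(table)}")
    return ModelConfig(**{**table[name], **overrides})


def uses_contrastive(name: str) -> bool:
    return name.startswith("s_")
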