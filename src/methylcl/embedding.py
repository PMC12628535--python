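"""Primary-view embedding backends.

The token stream from `sequence_io` is turned into a real feature matrix
X of shape (L0 - k + 3) x D either by

* ``lookup`` — a trainable embedding table initialised from a seeded normal
  scheme and optimised end-to-end with the rest of the network (default,
  D = 32), or
* ``pretrained`` — final-layer per-token representations of a frozen
  pretrained DNA language model (D = 768), loaded from a local directory via
  the ``transformers`` package when both are available.

The lookup backend ties weights by construction: every occurrence of a token
id reads the same table row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, embedding_lookup
from .sequence_io import TokenSequence, VALID_K, build_vocab

PRETRAINED_DIM = 768
DEFAULT_LOOKUP_DIM = 32


@dataclass(frozen=True)
class EmbeddedSequence:
    X: np.ndarray  # (tokens, D)
    D: int


@dataclass(frozen=True)
class BackendConfig:
    """Vocabulary and backend choice for one k-mer size (default k = 6)."""

    k: int
    backend: str  # "lookup" | "pretrained"
    dim: int
    vocab_size: int


def select_kmer_variant(
    k: int = 6, backend: str = "lookup", dim: int | None = None
) -> BackendConfig:
    if k not in VALID_K:
        raise ValueError(f"k must be one of {VALID_K}, got {k}")
    if backend not in ("lookup", "pretrained"):
        raise ValueError(f"unknown backend {backend!r}")
    if dim is None:
        dim = PRETRAINED_DIM if backend == "pretrained" else DEFAULT_LOOKUP_DIM
    return BackendConfig(k=k, backend=backend, dim=dim, vocab_size=4**k + 5)


class LookupEmbedding:
    """Trainable token-embedding table (the default backend)."""

    def __init__(self, vocab_size: int, dim: int, rng: np.random.Generator):
        self.weight = Tensor(rng.normal(0.0, 0.1, size=(vocab_size, dim)), requires_grad=True)
        self.vocab_size = vocab_size
        self.dim = dim

    def __call__(self, ids: np.ndarray) -> Tensor:
        return embedding_lookup(self.weight, np.asarray(ids))

    @property
    def parameters(self) -> list[Tensor]:
        return [self.weight]


class PretrainedEmbedding:
    """Frozen DNA language-model backend (feature-extractor mode).

    Requires the ``transformers`` package and a local model directory holding
    a k-mer DNA BERT checkpoint; nothing is downloaded.
    """

    def __init__(self, model_dir: str | None, k: int):
        if model_dir is None:
            raise RuntimeError(
                "pretrained backend needs a local model directory "
                "(embedding.model_dir); use backend='lookup' for a "
                "self-contained trainable embedding"
            )
        try:
            from transformers import AutoModel, AutoTokenizer  # noqa: F401
        except ImportError as exc:
            raise RuntimeError(
                "pretrained backend requires the 'transformers' package; "
                "install it or use backend='lookup'"
            ) from exc
        from transformers import AutoModel as _AutoModel

        self._model = _AutoModel.from_pretrained(model_dir)
        self._model.eval()
        self.k = k
        self.dim = PRETRAINED_DIM

    def __call__(self, ids: np.ndarray) -> Tensor:
        import torch

        with torch.no_grad():
            out = self._model(input_ids=torch.as_tensor(ids, dtype=torch.long))
        return Tensor(out.last_hidden_state.numpy())  # frozen: no grad

    @property
    def parameters(self) -> list[Tensor]:
        return []


def make_backend(
    config: BackendConfig,
    rng: np.random.Generator | None = None,
    model_dir: str | None = None,
):
    if config.backend == "lookup":
        if rng is None:
            rng = np.random.default_rng(0)
        return LookupEmbedding(config.vocab_size, config.dim, rng)
    return PretrainedEmbedding(model_dir, config.k)


def embed(tokens: TokenSequence, backend) -> EmbeddedSequence:
    """Embed one token sequence into its (tokens, D) feature matrix."""
    X = backend(np.asarray(tokens.ids)[None, :]).data[0]
    return EmbeddedSequence(X=X, D=X.shape[1])


__all__ = [
    "EmbeddedSequence",
    "BackendConfig",
    "select_kmer_variant",
    "LookupEmbedding",
    "PretrainedEmbedding",
    "make_backend",
    "embed",
    "build_vocab",
]
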