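"""Stochastic view generation for contrastive training.

Each sample is a multi-view feature set (X, X_extra): the embedded token
matrix and the CGR state matrix.  Two augmentation operators are sampled
independently per sample, producing the correlated positive pair used by the
NT-Xent loss.  Discrete-token features are randomly masked — an entry
survives when a uniform draw exceeds p_mask — and the continuous CGR states
receive additive Gaussian noise of scale eta.  The defaults p_mask = 0.15 and
eta = 0.01 are the grid-search optimum (p_mask over {0.05..0.25}, eta over
{0.005..0.04}).

Masking defaults to the element level of X; a per-token (whole-row) mode is
available via ``mask_granularity="token"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

GRID_P_MASK = (0.05, 0.10, 0.15, 0.20, 0.25)
GRID_ETA = (0.005, 0.01, 0.02, 0.03, 0.04)


@dataclass(frozen=True)
class AugmentationConfig:
    p_mask: float = 0.15
    eta: float = 0.01
    mask_granularity: str = "element"  # "element" | "token"

    def __post_init__(self):
        if not 0.0 <= self.p_mask <= 1.0:
            raise ValueError(f"p_mask must lie in [0, 1], got {self.p_mask}")
        if self.eta < 0.0:
            raise ValueError(f"eta must be non-negative, got {self.eta}")
        if self.mask_granularity not in ("element", "token"):
            raise ValueError(f"unknown mask granularity {self.mask_granularity!r}")


@dataclass(frozen=True)
class AugmentedPair:
    """Two independently augmented copies (query and key) of one sample."""

    view_q: tuple  # (X_aug_q, X_extra_aug_q)
    view_k: tuple  # (X_aug_k, X_extra_aug_k)


def sample_mask(shape: tuple, p_mask: float, rng: np.random.Generator) -> np.ndarray:
    """Binary keep-mask: entry is 1 iff U(0,1) > p_mask, so P(0) = p_mask."""
    if not 0.0 <= p_mask <= 1.0:
        raise ValueError(f"p_mask must lie in [0, 1], got {p_mask}")
    return (rng.uniform(size=shape) > p_mask).astype(np.float64)


def mask_features(X: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Hadamard product X * M; M may broadcast over the feature axis."""
    X = np.asarray(X, dtype=np.float64)
    M = np.asarray(M, dtype=np.float64)
    try:
        out = X * M
    except ValueError as exc:
        raise ValueError(f"mask shape {M.shape} incompatible with {X.shape}") from exc
    if out.shape != X.shape:
        raise ValueError(f"mask shape {M.shape} incompatible with {X.shape}")
    return out


def add_noise(X_extra: np.ndarray, eta: float, rng: np.random.Generator) -> np.ndarray:
    """Additive Gaussian noise: X + N(0,1) * eta."""
    if eta < 0.0:
        raise ValueError(f"eta must be non-negative, got {eta}")
    X_extra = np.asarray(X_extra, dtype=np.float64)
    if eta == 0.0:
        return X_extra.copy()
    return X_extra + rng.standard_normal(X_extra.shape) * eta


def _augment_once(
    X: np.ndarray,
    X_extra: np.ndarray,
    config: AugmentationConfig,
    rng: np.random.Generator,
) -> tuple:
    if config.mask_granularity == "token":
        M = sample_mask(X.shape[:-1] + (1,), config.p_mask, rng)
    else:
        M = sample_mask(X.shape, config.p_mask, rng)
    return mask_features(X, M), add_noise(X_extra, config.eta, rng)


def make_views(
    sample: tuple,
    config: AugmentationConfig,
    rng: np.random.Generator,
) -> AugmentedPair:
    """Draw two independent augmentation operators and apply both to `sample`."""
    X, X_extra = sample
    return AugmentedPair(
        view_q=_augment_once(X, X_extra, config, rng),
        view_k=_augment_once(X, X_extra, config, rng),
    )
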