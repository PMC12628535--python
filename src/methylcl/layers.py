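"""Trainable layers built on the autodiff engine.

Shapes follow the (batch, time, channels) convention throughout.  Weight
initialisation is Glorot-uniform from a caller-supplied seeded generator so
whole-model construction is reproducible.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, conv1d, matmul


def glorot(rng: np.random.Generator, shape: tuple, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = Tensor(glorot(rng, (d_in, d_out), d_in, d_out), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return matmul(x, self.W) + self.b

    @property
    def parameters(self):
        return [self.W, self.b]


class Conv1dLayer:
    """Same-padded 1-D convolution over the time axis."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        fan_in, fan_out = kernel * c_in, kernel * c_out
        self.W = Tensor(
            glorot(rng, (kernel, c_in, c_out), fan_in, fan_out), requires_grad=True
        )
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.W, self.b)

    @property
    def parameters(self):
        return [self.W, self.b]


class BatchNorm1d:
    """Per-channel normalisation over (batch, time); running stats for eval."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, train_mode: bool) -> Tensor:
        if train_mode:
            mu = x.mean(axis=(0, 1), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 1), keepdims=True)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mu.data.ravel()
            )
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var.data.ravel()
            )
            xhat = (x - mu) / ((var + self.eps) ** 0.5)
        else:
            xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return xhat * self.gamma + self.beta

    @property
    def parameters(self):
        return [self.gamma, self.beta]


class GroupNorm:
    """Per-sample normalisation over channel groups (and time)."""

    def __init__(self, channels: int, groups: int = 4, eps: float = 1e-5):
        if channels % groups != 0:
            raise ValueError(f"{channels} channels not divisible into {groups} groups")
        self.groups = groups
        self.eps = eps
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, C = x.shape
        g = self.groups
        xg = x.reshape(B, T, g, C // g)
        mu = xg.mean(axis=(1, 3), keepdims=True)
        var = ((xg - mu) ** 2).mean(axis=(1, 3), keepdims=True)
        xhat = ((xg - mu) / ((var + self.eps) ** 0.5)).reshape(B, T, C)
        return xhat * self.gamma + self.beta

    @property
    def parameters(self):
        return [self.gamma, self.beta]


def dropout(x: Tensor, rate: float, train_mode: bool, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; identity in eval mode or at rate 0."""
    if not train_mode or rate == 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.uniform(size=x.shape) < keep) / keep
    return x * Tensor(mask)


def _lstm_fused(x: Tensor, Wx: Tensor, Wh: Tensor, b: Tensor, reverse: bool) -> Tensor:
    """LSTM over the time axis as one autodiff node with hand-written BPTT.

    x: (B, T, Din); Wx: (Din, 4H); Wh: (H, 4H); b: (4H,). Gate order in the
    fused weights: input, forget, cell, output.  `reverse` processes time
    back-to-front (outputs are returned in original time order).  Fusing the
    whole recurrence into one node keeps the tape small; the gradient rule is
    checked against finite differences in the test suite.
    """
    xd = x.data[:, ::-1] if reverse else x.data
    B, T, Din = xd.shape
    H = Wh.data.shape[0]
    xproj = xd.reshape(B * T, Din) @ Wx.data + b.data
    xproj = xproj.reshape(B, T, 4 * H)
    i_s = np.empty((B, T, H)); f_s = np.empty((B, T, H))
    g_s = np.empty((B, T, H)); o_s = np.empty((B, T, H))
    tc_s = np.empty((B, T, H))  # tanh(c_t)
    hprev_s = np.empty((B, T, H)); cprev_s = np.empty((B, T, H))
    h = np.zeros((B, H)); c = np.zeros((B, H))
    for t in range(T):
        gates = xproj[:, t] + h @ Wh.data
        i = 1.0 / (1.0 + np.exp(-gates[:, :H]))
        f = 1.0 / (1.0 + np.exp(-gates[:, H : 2 * H]))
        g = np.tanh(gates[:, 2 * H : 3 * H])
        o = 1.0 / (1.0 + np.exp(-gates[:, 3 * H :]))
        hprev_s[:, t] = h; cprev_s[:, t] = c
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        i_s[:, t] = i; f_s[:, t] = f; g_s[:, t] = g; o_s[:, t] = o; tc_s[:, t] = tc
    out = np.stack(
        [o_s[:, t] * tc_s[:, t] for t in range(T)], axis=1
    )
    out_data = out[:, ::-1].copy() if reverse else out

    def backward(grad):
        gh_seq = grad[:, ::-1] if reverse else grad
        da_seq = np.empty((B, T, 4 * H))
        dh_next = np.zeros((B, H)); dc_next = np.zeros((B, H))
        WhT = Wh.data.T
        for t in range(T - 1, -1, -1):
            i, f, g, o, tc = i_s[:, t], f_s[:, t], g_s[:, t], o_s[:, t], tc_s[:, t]
            dh = gh_seq[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc**2) + dc_next
            di = dc * g
            df = dc * cprev_s[:, t]
            dg = dc * i
            da = da_seq[:, t]
            da[:, :H] = di * i * (1.0 - i)
            da[:, H : 2 * H] = df * f * (1.0 - f)
            da[:, 2 * H : 3 * H] = dg * (1.0 - g**2)
            da[:, 3 * H :] = do * o * (1.0 - o)
            dc_next = dc * f
            dh_next = da @ WhT
        da2 = da_seq.reshape(B * T, 4 * H)
        if x.requires_grad:
            dx = (da2 @ Wx.data.T).reshape(B, T, Din)
            x._accum(dx[:, ::-1] if reverse else dx)
        if Wx.requires_grad:
            Wx._accum(xd.reshape(B * T, Din).T @ da2)
        if Wh.requires_grad:
            Wh._accum(hprev_s.reshape(B * T, H).T @ da2)
        if b.requires_grad:
            b._accum(da2.sum(axis=0))

    return Tensor._make(out_data, (x, Wx, Wh, b), backward)


class LSTM:
    """Single-direction LSTM returning per-step hidden states."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.Wx = Tensor(
            glorot(rng, (d_in, 4 * hidden), d_in, 4 * hidden), requires_grad=True
        )
        self.Wh = Tensor(
            glorot(rng, (hidden, 4 * hidden), hidden, 4 * hidden), requires_grad=True
        )
        b = np.zeros(4 * hidden)
        b[hidden : 2 * hidden] = 1.0  # forget-gate bias 1: remember by default
        self.b = Tensor(b, requires_grad=True)

    def __call__(self, x: Tensor, reverse: bool = False) -> Tensor:
        return _lstm_fused(x, self.Wx, self.Wh, self.b, reverse)

    @property
    def parameters(self):
        return [self.Wx, self.Wh, self.b]


class BiLSTM:
    """Bidirectional LSTM; per-step outputs are the concatenated directions."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        self.fwd = LSTM(d_in, hidden, rng)
        self.bwd = LSTM(d_in, hidden, rng)
        self.hidden = hidden

    def __call__(self, x: Tensor) -> Tensor:
        return concat([self.fwd(x), self.bwd(x, reverse=True)], axis=2)

    def final_states(self, outputs: Tensor) -> Tensor:
        """Summary vector: forward state at t=T-1 ++ backward state at t=0."""
        H = self.hidden
        return concat([outputs[:, -1, :H], outputs[:, 0, H:]], axis=1)

    @property
    def parameters(self):
        return self.fwd.parameters + self.bwd.parameters
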