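"""Minimal NumPy neural-network layers with explicit backpropagation.

Each layer is a stateless pair of functions: ``forward`` returns the output
plus a cache, ``backward`` consumes the upstream gradient and the cache and
returns input and parameter gradients.  Parameters live in plain dicts of
float64 arrays so the optimizer and checkpointing stay trivial.  The layer
set is exactly what the sequence-regression model needs: embedding lookup,
LSTM recurrence, linear maps, same-length 1-D convolution, ReLU and
inverted dropout, plus an Adam optimizer.
"""

from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable piecewise form
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


# ---------------------------------------------------------------------------
# embedding


def embedding_forward(indices: np.ndarray, table: np.ndarray):
    """indices (B, T) int -> (B, T, D) rows of ``table``."""
    return table[indices], (indices, table.shape)


def embedding_backward(dout: np.ndarray, cache):
    indices, shape = cache
    dtable = np.zeros(shape, dtype=np.float64)
    np.add.at(dtable, indices.ravel(), dout.reshape(-1, shape[1]))
    return dtable


# ---------------------------------------------------------------------------
# linear


def linear_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray | None):
    out = x @ W
    if b is not None:
        out = out + b
    return out, (x, W, b is not None)


def linear_backward(dout: np.ndarray, cache):
    x, W, has_bias = cache
    dx = dout @ W.T
    dW = x.reshape(-1, x.shape[-1]).T @ dout.reshape(-1, dout.shape[-1])
    db = dout.reshape(-1, dout.shape[-1]).sum(axis=0) if has_bias else None
    return dx, dW, db


# ---------------------------------------------------------------------------
# LSTM (single direction). Gate order: input, forget, cell, output.


def lstm_forward(x: np.ndarray, Wx: np.ndarray, Wh: np.ndarray, b: np.ndarray):
    """x (B, T, D) -> hidden states (B, T, H).

    Initial hidden and cell states are zero.  The input projection for all
    timesteps is computed in one matmul; the time loop only carries the
    recurrent part.
    """
    B, T, D = x.shape
    H = Wh.shape[0]
    ax = x.reshape(-1, D) @ Wx + b  # (B*T, 4H)
    ax = ax.reshape(B, T, 4 * H)
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    hs = np.empty((B, T, H))
    gates = np.empty((B, T, 4 * H))  # post-activation i, f, g, o
    cs = np.empty((B, T, H))
    tanh_cs = np.empty((B, T, H))
    for t in range(T):
        a = ax[:, t, :] + h @ Wh
        i = sigmoid(a[:, :H])
        f = sigmoid(a[:, H : 2 * H])
        g = np.tanh(a[:, 2 * H : 3 * H])
        o = sigmoid(a[:, 3 * H :])
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        hs[:, t, :] = h
        cs[:, t, :] = c
        gates[:, t, 0:H] = i
        gates[:, t, H : 2 * H] = f
        gates[:, t, 2 * H : 3 * H] = g
        gates[:, t, 3 * H :] = o
        tanh_cs[:, t, :] = tc
    cache = (x, Wx, Wh, hs, cs, gates, tanh_cs)
    return hs, cache


def lstm_backward(dhs: np.ndarray, cache):
    """dhs (B, T, H) -> (dx, dWx, dWh, db)."""
    x, Wx, Wh, hs, cs, gates, tanh_cs = cache
    B, T, D = x.shape
    H = Wh.shape[0]
    da = np.empty((B, T, 4 * H))
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    dWh = np.zeros_like(Wh)
    for t in range(T - 1, -1, -1):
        dh = dhs[:, t, :] + dh_next
        i = gates[:, t, 0:H]
        f = gates[:, t, H : 2 * H]
        g = gates[:, t, 2 * H : 3 * H]
        o = gates[:, t, 3 * H :]
        tc = tanh_cs[:, t, :]
        c_prev = cs[:, t - 1, :] if t > 0 else np.zeros((B, H))
        h_prev = hs[:, t - 1, :] if t > 0 else np.zeros((B, H))
        do = dh * tc
        dc = dc_next + dh * o * (1.0 - tc * tc)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dc_next = dc * f
        dat = da[:, t, :]
        dat[:, 0:H] = di * i * (1.0 - i)
        dat[:, H : 2 * H] = df * f * (1.0 - f)
        dat[:, 2 * H : 3 * H] = dg * (1.0 - g * g)
        dat[:, 3 * H :] = do * o * (1.0 - o)
        dWh += h_prev.T @ dat
        dh_next = dat @ Wh.T
    da_flat = da.reshape(-1, 4 * H)
    dWx = x.reshape(-1, D).T @ da_flat
    db = da_flat.sum(axis=0)
    dx = (da_flat @ Wx.T).reshape(B, T, D)
    return dx, dWx, dWh, db


# ---------------------------------------------------------------------------
# same-length 1-D convolution along the time axis
# kernel K has shape (ksize, C_in, C_out); input (B, T, C_in)


def conv1d_forward(x: np.ndarray, K: np.ndarray, b: np.ndarray):
    ksize, c_in, c_out = K.shape
    pad = (ksize - 1) // 2
    B, T, _ = x.shape
    xp = np.zeros((B, T + 2 * pad, c_in))
    xp[:, pad : pad + T, :] = x
    out = np.tile(b, (B, T, 1))
    for j in range(ksize):
        out += xp[:, j : j + T, :] @ K[j]
    return out, (xp, K, x.shape)


def conv1d_backward(dout: np.ndarray, cache):
    xp, K, x_shape = cache
    ksize, c_in, c_out = K.shape
    pad = (ksize - 1) // 2
    B, T, _ = x_shape
    dxp = np.zeros_like(xp)
    dK = np.zeros_like(K)
    dflat = dout.reshape(-1, c_out)
    for j in range(ksize):
        dK[j] = xp[:, j : j + T, :].reshape(-1, c_in).T @ dflat
        dxp[:, j : j + T, :] += dout @ K[j].T
    db = dflat.sum(axis=0)
    dx = dxp[:, pad : pad + T, :]
    return dx, dK, db


# ---------------------------------------------------------------------------
# activations / dropout


def relu_forward(x: np.ndarray):
    out = np.maximum(x, 0.0)
    return out, x > 0


def relu_backward(dout: np.ndarray, mask):
    return dout * mask


def dropout_forward(x: np.ndarray, rate: float, rng, training: bool):
    """Inverted dropout; identity in evaluation mode or at rate 0."""
    if not training or rate <= 0.0:
        return x, None
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * mask, mask

def dropout_backward(dout: np.ndarray, mask):
    return dout if mask is None else dout * mask


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    """Adaptive moment estimation over a dict of named parameters."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            m = self.m[k]
            v = self.v[k]
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            params[k] -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)
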