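"""Independent straight-line reference implementations of the network's
building blocks, written with explicit Python loops so they share no code
path with the package.  Used to cross-check the vectorized implementation
on small random instances."""

from __future__ import annotations

import math

import numpy as np


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def ref_lstm(x: np.ndarray, Wx: np.ndarray, Wh: np.ndarray,
             b: np.ndarray) -> np.ndarray:
    """Single-direction LSTM over one sequence x (T, D) -> (T, H)."""
    T, D = x.shape
    H = Wh.shape[0]
    h = np.zeros(H)
    c = np.zeros(H)
    out = np.zeros((T, H))
    for t in range(T):
        a = x[t] @ Wx + h @ Wh + b
        i = np.array([_sigmoid(v) for v in a[:H]])
        f = np.array([_sigmoid(v) for v in a[H : 2 * H]])
        g = np.tanh(a[2 * H : 3 * H])
        o = np.array([_sigmoid(v) for v in a[3 * H :]])
        c = f * c + i * g
        h = o * np.tanh(c)
        out[t] = h
    return out


def ref_bilstm_encode(x: np.ndarray, params: dict, num_layers: int,
                      H: int) -> np.ndarray:
    """Stacked bidirectional encoding of one sequence (T, D) -> C (T, H).

    Intermediate layers pass the concatenated directional states; the top
    layer fuses them with the learned maps We (backward) and Wv (forward).
    """
    for layer in range(num_layers):
        kf, kb = f"lstm{layer}_f", f"lstm{layer}_b"
        hf = ref_lstm(x, params[f"{kf}_Wx"], params[f"{kf}_Wh"], params[f"{kf}_b"])
        hb = ref_lstm(
            x[::-1], params[f"{kb}_Wx"], params[f"{kb}_Wh"], params[f"{kb}_b"]
        )[::-1]
        if layer < num_layers - 1:
            x = np.concatenate([hf, hb], axis=1)
        else:
            return hf @ params["fuse_Wv"] + hb @ params["fuse_We"]
    raise AssertionError("unreachable")


def ref_channel_attention(C: np.ndarray, W0: np.ndarray,
                          W1: np.ndarray) -> np.ndarray:
    """Channel map for one state sequence C (T, H) -> (H,)."""
    T, H = C.shape
    c_avg = np.array([C[:, j].sum() / T for j in range(H)])
    c_max = np.array([max(C[:, j]) for j in range(H)])

    def mlp(v):
        hidden = v @ W0
        hidden = np.array([max(0.0, u) for u in hidden])
        return hidden @ W1

    return mlp(c_avg) + mlp(c_max)


def ref_spatial_attention(C: np.ndarray, K1, b1, K2, b2) -> np.ndarray:
    """Spatial map for one state sequence C (T, H) -> (T,) by explicit
    sliding-window evaluation of both kernel-7 convolutions."""
    T, H = C.shape
    ksize = K1.shape[0]
    pad = (ksize - 1) // 2
    F1 = K1.shape[2]
    s1 = np.zeros((T, F1))
    for t in range(T):
        for f in range(F1):
            acc = b1[f]
            for j in range(ksize):
                src = t + j - pad
                if 0 <= src < T:
                    for h in range(H):
                        acc += C[src, h] * K1[j, h, f]
            s1[t, f] = acc
    r1 = np.maximum(s1, 0.0)
    ms = np.zeros(T)
    for t in range(T):
        acc = b2[0]
        for j in range(ksize):
            src = t + j - pad
            if 0 <= src < T:
                for f in range(F1):
                    acc += r1[src, f] * K2[j, f, 0]
        ms[t] = acc
    return ms


def ref_fuse_and_pool(C: np.ndarray, Mc: np.ndarray,
                      Ms: np.ndarray) -> np.ndarray:
    """Elementwise sigmoid gating and position average for one sequence."""
    T, H = C.shape
    O = np.zeros(H)
    for j in range(H):
        total = 0.0
        for t in range(T):
            gate = _sigmoid(Mc[j] + Ms[t])
            total += gate * C[t, j]
        O[j] = total / T
    return O


def ref_dense_head(O: np.ndarray, W1, b1, W2, b2) -> float:
    """Two dense layers with ReLU between, evaluation mode."""
    hidden = O @ W1 + b1
    hidden = np.array([max(0.0, u) for u in hidden])
    return float((hidden @ W2 + b2)[0])
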