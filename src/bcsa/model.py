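"""The BCSA network for scalar property regression over SMILES tokens.

Architecture: a trainable token embedding, a stack of bidirectional LSTM
layers whose top-layer directional states are fused by learned linear maps
(h_t = We h_t<- + Wv h_t->), parallel channel and spatial attention over the
resulting state sequence C fused through one sigmoid gate
(C' = sigma(Mc + Ms) (x) C), average pooling over positions, and a two-layer
feed-forward head producing one real value per molecule.

Channel attention pools C per channel (average and max over positions) and
passes both descriptors through one shared bottleneck MLP; spatial attention
runs two kernel-7 1-D convolutions along the position axis.  No padding mask
is applied anywhere: pad positions carry the pad embedding and participate
in attention and pooling.

Everything is NumPy with explicit backpropagation (see :mod:`bcsa.nn`);
:meth:`BCSARegressor.forward` is the training entry point and the
intermediate stages are exposed as evaluation-mode methods for inspection
and testing.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .tokenizer import Vocabulary


@dataclass
class ModelConfig:
    """Hyperparameters of the network and its training.

    Defaults are the reference full-scale configuration (batch 1024,
    vocabulary 120, sequence length 150, hidden size 64, 3 stacked layers,
    dropout 0.12215, head width 32, learning rate 0.00966).
    ``embed_dim`` defaults to ``hidden_size``; ``channel_reduction`` is the
    bottleneck divisor of the shared channel-attention MLP.
    """

    batch_size: int = 1024
    vocab_size: int = 120
    smiles_max_len: int = 150
    hidden_size: int = 64
    num_layers: int = 3
    dropout: float = 0.12215
    mlp_hidden_size: int = 32
    learning_rate: float = 0.00966
    embed_dim: int | None = None
    channel_reduction: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("batch_size", "vocab_size", "smiles_max_len",
                     "hidden_size", "num_layers", "mlp_hidden_size",
                     "channel_reduction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.embed_dim is None:
            self.embed_dim = self.hidden_size

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


# ---------------------------------------------------------------------------
# standalone attention/fusion computations (forward only)


def channel_attention(C: np.ndarray, W0: np.ndarray, W1: np.ndarray) -> np.ndarray:
    """Channel map Mc: shared MLP over average- and max-pooled descriptors.

    ``C`` is (batch, n, hidden); the result has shape (batch, hidden).
    """
    c_avg = C.mean(axis=1)
    c_max = C.max(axis=1)
    return nn.relu(c_avg @ W0) @ W1 + nn.relu(c_max @ W0) @ W1


def spatial_attention(C: np.ndarray, K1, b1, K2, b2) -> np.ndarray:
    """Spatial map Ms over positions: Conv1d(7, 16) -> ReLU -> Conv1d(7, 1)."""
    s1, _ = nn.conv1d_forward(C, K1, b1)
    s2, _ = nn.conv1d_forward(nn.relu(s1), K2, b2)
    return s2[:, :, 0]


def fuse_and_pool(C: np.ndarray, Mc: np.ndarray, Ms: np.ndarray) -> np.ndarray:
    """Gate C by sigma(Mc + Ms) and average-pool over positions."""
    gate = nn.sigmoid(Mc[:, None, :] + Ms[:, :, None])
    return (gate * C).mean(axis=1)


class BCSARegressor:
    """Bidirectional LSTM with channel/spatial attention, NumPy backend."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.params: dict[str, np.ndarray] = {}
        self._init_params(np.random.default_rng(config.seed))
        # generator used only for dropout masks during training
        self._dropout_rng = np.random.default_rng(config.seed + 1)

    # -- parameter initialisation ------------------------------------------

    def _init_params(self, rng) -> None:
        cfg = self.config
        H = cfg.hidden_size
        p = self.params

        def uniform(shape, fan_in):
            k = 1.0 / np.sqrt(fan_in)
            return rng.uniform(-k, k, size=shape)

        p["embed"] = uniform((cfg.vocab_size, cfg.embed_dim), cfg.embed_dim)
        d_in = cfg.embed_dim
        for layer in range(cfg.num_layers):
            for direction in ("f", "b"):
                key = f"lstm{layer}_{direction}"
                p[f"{key}_Wx"] = uniform((d_in, 4 * H), H)
                p[f"{key}_Wh"] = uniform((H, 4 * H), H)
                p[f"{key}_b"] = uniform((4 * H,), H)
            d_in = 2 * H  # stacked layers consume both directions
        p["fuse_Wv"] = uniform((H, H), H)  # forward direction
        p["fuse_We"] = uniform((H, H), H)  # backward direction
        bottleneck = max(1, H // cfg.channel_reduction)
        p["ca_W0"] = uniform((H, bottleneck), H)
        p["ca_W1"] = uniform((bottleneck, H), bottleneck)
        p["sa_K1"] = uniform((7, H, 16), 7 * H)
        p["sa_b1"] = uniform((16,), 7 * H)
        p["sa_K2"] = uniform((7, 16, 1), 7 * 16)
        p["sa_b2"] = uniform((1,), 7 * 16)
        p["head_W1"] = uniform((H, cfg.mlp_hidden_size), H)
        p["head_b1"] = uniform((cfg.mlp_hidden_size,), H)
        p["head_W2"] = uniform((cfg.mlp_hidden_size, 1), cfg.mlp_hidden_size)
        p["head_b2"] = uniform((1,), cfg.mlp_hidden_size)

    # -- forward -----------------------------------------------------------

    def forward(self, indices: np.ndarray, training: bool = False):
        """Predict one value per row of an integer index matrix.

        ``indices`` is (batch, n) with entries below ``vocab_size``.  Returns
        ``(predictions, cache)``; the cache feeds :meth:`backward`.  Dropout
        is active only with ``training=True``; evaluation-mode output is
        deterministic.
        """
        indices = np.atleast_2d(np.asarray(indices, dtype=np.int64))
        if indices.size and indices.max() >= self.config.vocab_size:
            raise ValueError(
                f"token index {indices.max()} >= vocab_size "
                f"{self.config.vocab_size}"
            )
        if indices.shape[0] == 0:
            raise ValueError("batch is empty")
        p = self.params
        cfg = self.config
        rng = self._dropout_rng
        cache: dict = {}

        x, cache["embed"] = nn.embedding_forward(indices, p["embed"])

        lstm_caches = []
        for layer in range(cfg.num_layers):
            kf, kb = f"lstm{layer}_f", f"lstm{layer}_b"
            hf, cf = nn.lstm_forward(x, p[f"{kf}_Wx"], p[f"{kf}_Wh"], p[f"{kf}_b"])
            hb_rev, cb = nn.lstm_forward(
                x[:, ::-1, :], p[f"{kb}_Wx"], p[f"{kb}_Wh"], p[f"{kb}_b"]
            )
            hb = hb_rev[:, ::-1, :]
            if layer < cfg.num_layers - 1:
                stacked = np.concatenate([hf, hb], axis=2)
                stacked, dmask = nn.dropout_forward(
                    stacked, cfg.dropout, rng, training
                )
                lstm_caches.append((cf, cb, dmask, None, None))
                x = stacked
            else:
                # top layer: learned-weight sum of the two directions
                C = hf @ p["fuse_Wv"] + hb @ p["fuse_We"]
                lstm_caches.append((cf, cb, None, hf, hb))
        cache["lstm"] = lstm_caches
        cache["C"] = C

        # channel attention (shared bottleneck MLP, no bias)
        c_avg = C.mean(axis=1)
        amax = C.argmax(axis=1)
        c_max = np.take_along_axis(C, amax[:, None, :], axis=1)[:, 0, :]
        za, ma = nn.relu_forward(c_avg @ p["ca_W0"])
        zm, mm = nn.relu_forward(c_max @ p["ca_W0"])
        Mc = za @ p["ca_W1"] + zm @ p["ca_W1"]
        cache["channel"] = (c_avg, c_max, amax, za, ma, zm, mm)

        # spatial attention
        s1, conv1_cache = nn.conv1d_forward(C, p["sa_K1"], p["sa_b1"])
        r1, rmask1 = nn.relu_forward(s1)
        s2, conv2_cache = nn.conv1d_forward(r1, p["sa_K2"], p["sa_b2"])
        Ms = s2[:, :, 0]
        cache["spatial"] = (conv1_cache, rmask1, conv2_cache)

        # fuse by one sigmoid gate, average-pool over positions
        gate = nn.sigmoid(Mc[:, None, :] + Ms[:, :, None])
        Cp = gate * C
        O = Cp.mean(axis=1)
        cache["fuse"] = (gate, C)
        cache["Mc"], cache["Ms"], cache["O"] = Mc, Ms, O

        # two dense layers with dropout before each
        d0, dm0 = nn.dropout_forward(O, cfg.dropout, rng, training)
        z1, lin1_cache = nn.linear_forward(d0, p["head_W1"], p["head_b1"])
        r1h, rmaskh = nn.relu_forward(z1)
        d1, dm1 = nn.dropout_forward(r1h, cfg.dropout, rng, training)
        y, lin2_cache = nn.linear_forward(d1, p["head_W2"], p["head_b2"])
        cache["head"] = (dm0, lin1_cache, rmaskh, dm1, lin2_cache)
        return y[:, 0], cache

    def predict(self, indices: np.ndarray) -> np.ndarray:
        """Evaluation-mode predictions (no dropout, deterministic)."""
        preds, _ = self.forward(indices, training=False)
        return preds

    # -- backward ----------------------------------------------------------

    def backward(self, dpred: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss w.r.t. every parameter.

        ``dpred`` is d(loss)/d(prediction), shape (batch,).
        """
        p = self.params
        cfg = self.config
        grads: dict[str, np.ndarray] = {}

        dm0, lin1_cache, rmaskh, dm1, lin2_cache = cache["head"]
        dy = dpred[:, None]
        dd1, grads["head_W2"], grads["head_b2"] = nn.linear_backward(dy, lin2_cache)
        dr1h = nn.dropout_backward(dd1, dm1)
        dz1 = nn.relu_backward(dr1h, rmaskh)
        dd0, grads["head_W1"], grads["head_b1"] = nn.linear_backward(dz1, lin1_cache)
        dO = nn.dropout_backward(dd0, dm0)

        gate, C = cache["fuse"]
        B, T, H = C.shape
        dCp = dO[:, None, :] / T  # mean-pool broadcast
        dgate = dCp * C
        dC = dCp * gate
        dpre = dgate * gate * (1.0 - gate)  # sigmoid
        dMc = dpre.sum(axis=1)
        dMs = dpre.sum(axis=2)

        conv1_cache, rmask1, conv2_cache = cache["spatial"]
        dr1, grads["sa_K2"], grads["sa_b2"] = nn.conv1d_backward(
            dMs[:, :, None], conv2_cache
        )
        ds1 = nn.relu_backward(dr1, rmask1)
        dC_sa, grads["sa_K1"], grads["sa_b1"] = nn.conv1d_backward(ds1, conv1_cache)
        dC += dC_sa

        c_avg, c_max, amax, za, ma, zm, mm = cache["channel"]
        grads["ca_W1"] = za.T @ dMc + zm.T @ dMc
        dza = nn.relu_backward(dMc @ p["ca_W1"].T, ma)
        dzm = nn.relu_backward(dMc @ p["ca_W1"].T, mm)
        grads["ca_W0"] = c_avg.T @ dza + c_max.T @ dzm
        dc_avg = dza @ p["ca_W0"].T
        dc_max = dzm @ p["ca_W0"].T
        dC += dc_avg[:, None, :] / T
        dC_max = np.zeros_like(dC)
        np.put_along_axis(dC_max, amax[:, None, :], dc_max[:, None, :], axis=1)
        dC += dC_max

        # through the LSTM stack, top layer first
        lstm_caches = cache["lstm"]
        dx = None
        for layer in range(cfg.num_layers - 1, -1, -1):
            cf, cb, dmask, hf, hb = lstm_caches[layer]
            kf, kb = f"lstm{layer}_f", f"lstm{layer}_b"
            if layer == cfg.num_layers - 1:
                grads["fuse_Wv"] = hf.reshape(-1, H).T @ dC.reshape(-1, H)
                grads["fuse_We"] = hb.reshape(-1, H).T @ dC.reshape(-1, H)
                dhf = dC @ p["fuse_Wv"].T
                dhb = dC @ p["fuse_We"].T
            else:
                dstacked = nn.dropout_backward(dx, dmask)
                dhf = dstacked[:, :, :H]
                dhb = dstacked[:, :, H:]
            dx_f, grads[f"{kf}_Wx"], grads[f"{kf}_Wh"], grads[f"{kf}_b"] = (
                nn.lstm_backward(dhf, cf)
            )
            dx_b_rev, grads[f"{kb}_Wx"], grads[f"{kb}_Wh"], grads[f"{kb}_b"] = (
                nn.lstm_backward(dhb[:, ::-1, :], cb)
            )
            dx = dx_f + dx_b_rev[:, ::-1, :]

        grads["embed"] = nn.embedding_backward(dx, cache["embed"])
        return grads

    # -- spec-level stage methods (evaluation mode) ------------------------

    def embed(self, indices: np.ndarray) -> np.ndarray:
        """Token indices -> embedding matrix M, shape (n, embed_dim)."""
        indices = np.asarray(indices, dtype=np.int64)
        if indices.size and indices.max() >= self.config.vocab_size:
            raise ValueError("token index out of range")
        return self.params["embed"][indices]

    def bilstm_encode(self, M: np.ndarray) -> np.ndarray:
        """Embedding matrix (n, l) or batch (B, n, l) -> state sequence C."""
        x = M[None] if M.ndim == 2 else M
        p = self.params
        for layer in range(self.config.num_layers):
            kf, kb = f"lstm{layer}_f", f"lstm{layer}_b"
            hf, _ = nn.lstm_forward(x, p[f"{kf}_Wx"], p[f"{kf}_Wh"], p[f"{kf}_b"])
            hb_rev, _ = nn.lstm_forward(
                x[:, ::-1, :], p[f"{kb}_Wx"], p[f"{kb}_Wh"], p[f"{kb}_b"]
            )
            hb = hb_rev[:, ::-1, :]
            if layer < self.config.num_layers - 1:
                x = np.concatenate([hf, hb], axis=2)
            else:
                C = hf @ p["fuse_Wv"] + hb @ p["fuse_We"]
        return C[0] if M.ndim == 2 else C

    def channel_attention(self, C: np.ndarray) -> np.ndarray:
        C = C[None] if C.ndim == 2 else C
        out = channel_attention(C, self.params["ca_W0"], self.params["ca_W1"])
        return out[0] if out.shape[0] == 1 else out

    def spatial_attention(self, C: np.ndarray) -> np.ndarray:
        squeeze = C.ndim == 2
        C = C[None] if squeeze else C
        p = self.params
        out = spatial_attention(C, p["sa_K1"], p["sa_b1"], p["sa_K2"], p["sa_b2"])
        return out[0] if squeeze else out

    def predict_head(self, O: np.ndarray) -> np.ndarray:
        squeeze = O.ndim == 1
        O = O[None] if squeeze else O
        p = self.params
        h = nn.relu(O @ p["head_W1"] + p["head_b1"])
        y = (h @ p["head_W2"] + p["head_b2"])[:, 0]
        return y[0] if squeeze else y

    # -- serialization -----------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=np.float64).copy()

    def save(self, path: str | Path, vocab: Vocabulary | None = None,
             max_len: int | None = None) -> None:
        """Write parameters + config (and optionally the vocabulary) to one
        ``.npz`` checkpoint; loading restores bit-identical evaluation output."""
        meta = {"config": self.config.to_dict()}
        if vocab is not None:
            meta["vocab"] = vocab.token_to_index
        if max_len is not None:
            meta["max_len"] = max_len
        arrays = dict(self.params)
        arrays["__meta__"] = np.frombuffer(
            json.dumps(meta).encode("utf-8"), dtype=np.uint8
        )
        with open(path, "wb") as fh:
            np.savez(fh, **arrays)

    @classmethod
    def load(cls, path: str | Path):
        """Return ``(model, vocab_or_None)`` from a checkpoint file."""
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode("utf-8"))
            model = cls(ModelConfig.from_dict(meta["config"]))
            model.load_state_dict(
                {k: data[k] for k in data.files if k != "__meta__"}
            )
        vocab = None
        if "vocab" in meta:
            vocab = Vocabulary(dict(meta["vocab"]))
        return model, vocab
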