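"""Bidirectional LSTM sequence-labeling network in plain numpy.

Forward and backward LSTM passes, a softmax token classifier over the
concatenated states, masked cross-entropy, full backpropagation through
time, and a Nadam (Nesterov-momentum Adam) optimizer.  Inputs per token
are the concatenation of a trainable word-lookup embedding, static
provider features (character-hash or pretrained vectors), and one
trainable low-dimensional embedding per auxiliary BIO channel.

Everything is seeded and dense float64; the intended scale is clinical
family-history sentences (tens of tokens), where this is fast on one CPU.
The analytic gradients are exercised against finite differences in the
test suite.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

Arrays = Dict[str, np.ndarray]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def init_params(
    rng: np.random.Generator,
    vocab_size: int,
    lookup_dim: int,
    static_dim: int,
    channel_sizes: Sequence[int],
    channel_dim: int,
    hidden: int,
    n_labels: int,
) -> Arrays:
    d_in = lookup_dim + static_dim + channel_dim * len(channel_sizes)

    def uniform(*shape: int) -> np.ndarray:
        bound = np.sqrt(6.0 / sum(shape[-2:])) if len(shape) > 1 else 0.08
        return rng.uniform(-bound, bound, size=shape)

    params: Arrays = {"E": rng.normal(0.0, 0.1, size=(vocab_size, lookup_dim))}
    for k, size in enumerate(channel_sizes):
        params[f"C{k}"] = rng.normal(0.0, 0.1, size=(size, channel_dim))
    for d in ("f", "b"):
        params[f"Wx_{d}"] = uniform(d_in, 4 * hidden)
        params[f"Wh_{d}"] = uniform(hidden, 4 * hidden)
        bias = np.zeros(4 * hidden)
        bias[hidden:2 * hidden] = 1.0  # forget-gate bias
        params[f"b_{d}"] = bias
    params["Wo"] = uniform(2 * hidden, n_labels)
    params["bo"] = np.zeros(n_labels)
    return params


def _lstm_forward(X: np.ndarray, mask: np.ndarray, Wx: np.ndarray,
                  Wh: np.ndarray, b: np.ndarray, hidden: int):
    T, B, _ = X.shape
    H = np.zeros((T, B, hidden))
    cache = []
    h = np.zeros((B, hidden))
    c = np.zeros((B, hidden))
    for t in range(T):
        z = X[t] @ Wx + h @ Wh + b
        i = _sigmoid(z[:, :hidden])
        f = _sigmoid(z[:, hidden:2 * hidden])
        g = np.tanh(z[:, 2 * hidden:3 * hidden])
        o = _sigmoid(z[:, 3 * hidden:])
        m = mask[t][:, None]
        c_new = (f * c + i * g) * m
        tanh_c = np.tanh(c_new)
        h_new = o * tanh_c * m
        cache.append((X[t], h, c, i, f, g, o, c_new, tanh_c, m))
        h, c = h_new, c_new
        H[t] = h
    return H, cache


def _lstm_backward(dH: np.ndarray, cache, Wx: np.ndarray, Wh: np.ndarray,
                   hidden: int):
    T = dH.shape[0]
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(Wx.shape[1])
    dX = np.zeros((T,) + cache[0][0].shape)
    dh_next = np.zeros((dH.shape[1], hidden))
    dc_next = np.zeros_like(dh_next)
    for t in range(T - 1, -1, -1):
        x_t, h_prev, c_prev, i, f, g, o, c_new, tanh_c, m = cache[t]
        dh = dH[t] + dh_next
        dh_raw = dh * m
        do = dh_raw * tanh_c
        dc = dc_next + dh_raw * o * (1.0 - tanh_c ** 2)
        du = dc * m
        df = du * c_prev
        di = du * g
        dg = du * i
        dc_next = du * f
        dz = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g ** 2), do * o * (1 - o)],
            axis=1,
        )
        dWx += x_t.T @ dz
        dWh += h_prev.T @ dz
        db += dz.sum(axis=0)
        dX[t] = dz @ Wx.T
        dh_next = dz @ Wh.T
    return dX, dWx, dWh, db


class Batch:
    """Padded batch of sentences: token ids, static features, channel label
    ids, gold label ids, and a validity mask, all time-major."""

    def __init__(self, ids: np.ndarray, static: np.ndarray,
                 channels: List[np.ndarray], labels: Optional[np.ndarray],
                 mask: np.ndarray) -> None:
        self.ids, self.static, self.channels = ids, static, channels
        self.labels, self.mask = labels, mask


def _compose_input(params: Arrays, batch: Batch) -> np.ndarray:
    parts = [params["E"][batch.ids]]
    if batch.static.shape[-1]:
        parts.append(batch.static)
    for k, ch in enumerate(batch.channels):
        parts.append(params[f"C{k}"][ch])
    return np.concatenate(parts, axis=-1)


def forward(params: Arrays, batch: Batch, hidden: int,
            dropout: float = 0.0, rng: Optional[np.random.Generator] = None):
    """Returns (logits, cache).  Dropout (inverted) is applied to the
    concatenated bidirectional state when ``dropout > 0`` and an rng is
    given (training mode only)."""
    X = _compose_input(params, batch)
    Hf, cache_f = _lstm_forward(X, batch.mask, params["Wx_f"], params["Wh_f"],
                                params["b_f"], hidden)
    Xr, Mr = X[::-1], batch.mask[::-1]
    Hb_r, cache_b = _lstm_forward(Xr, Mr, params["Wx_b"], params["Wh_b"],
                                  params["b_b"], hidden)
    Hb = Hb_r[::-1]
    Hcat = np.concatenate([Hf, Hb], axis=-1)
    if dropout > 0.0 and rng is not None:
        keep = (rng.random(Hcat.shape) >= dropout).astype(Hcat.dtype) / (1.0 - dropout)
    else:
        keep = None
    Hdrop = Hcat if keep is None else Hcat * keep
    logits = Hdrop @ params["Wo"] + params["bo"]
    cache = (X, cache_f, cache_b, Hdrop, keep)
    return logits, cache


def loss_and_grads(params: Arrays, batch: Batch, hidden: int,
                   dropout: float = 0.0,
                   rng: Optional[np.random.Generator] = None
                   ) -> Tuple[float, Arrays]:
    logits, (X, cache_f, cache_b, Hdrop, keep) = forward(
        params, batch, hidden, dropout=dropout, rng=rng)
    T, B, L = logits.shape
    shifted = logits - logits.max(axis=-1, keepdims=True)
    expl = np.exp(shifted)
    probs = expl / expl.sum(axis=-1, keepdims=True)
    n_tokens = max(batch.mask.sum(), 1.0)
    idx_t, idx_b = np.meshgrid(np.arange(T), np.arange(B), indexing="ij")
    logp = shifted - np.log(expl.sum(axis=-1, keepdims=True))
    nll = -(logp[idx_t, idx_b, batch.labels] * batch.mask).sum() / n_tokens

    dlogits = probs.copy()
    dlogits[idx_t, idx_b, batch.labels] -= 1.0
    dlogits *= batch.mask[..., None] / n_tokens

    grads: Arrays = {
        "Wo": np.tensordot(Hdrop, dlogits, axes=((0, 1), (0, 1))),
        "bo": dlogits.sum(axis=(0, 1)),
    }
    dHdrop = dlogits @ params["Wo"].T
    dHcat = dHdrop if keep is None else dHdrop * keep
    dHf = dHcat[..., :hidden]
    dHb = dHcat[..., hidden:]
    dXf, grads["Wx_f"], grads["Wh_f"], grads["b_f"] = _lstm_backward(
        dHf, cache_f, params["Wx_f"], params["Wh_f"], hidden)
    dXb_r, grads["Wx_b"], grads["Wh_b"], grads["b_b"] = _lstm_backward(
        dHb[::-1], cache_b, params["Wx_b"], params["Wh_b"], hidden)
    dX = dXf + dXb_r[::-1]

    # split dX back into lookup / static / channel segments
    lookup_dim = params["E"].shape[1]
    dE = np.zeros_like(params["E"])
    np.add.at(dE, batch.ids, dX[..., :lookup_dim])
    grads["E"] = dE
    offset = lookup_dim + batch.static.shape[-1]
    for k, ch in enumerate(batch.channels):
        cdim = params[f"C{k}"].shape[1]
        dC = np.zeros_like(params[f"C{k}"])
        np.add.at(dC, ch, dX[..., offset:offset + cdim])
        grads[f"C{k}"] = dC
        offset += cdim
    return float(nll), grads


class Nadam:
    """Nadam optimizer (Adam with Nesterov momentum), one state per array."""

    def __init__(self, params: Arrays, lr: float = 0.002, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: Arrays, grads: Arrays) -> None:
        self.t += 1
        b1, b2, t = self.b1, self.b2, self.t
        for k, g in grads.items():
            m = self.m[k] = b1 * self.m[k] + (1 - b1) * g
            v = self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = b1 * m / (1 - b1 ** (t + 1)) + (1 - b1) * g / (1 - b1 ** t)
            v_hat = v / (1 - b2 ** t)
            params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def predict_batch(params: Arrays, batch: Batch, hidden: int) -> np.ndarray:
    """Label-id predictions (T, B); deterministic (no dropout)."""
    logits, _ = forward(params, batch, hidden, dropout=0.0, rng=None)
    return logits.argmax(axis=-1)
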