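"""NumPy bidirectional LSTM with manual backpropagation.

Small, CPU-only sequence labeler: a stack of bidirectional LSTM layers
followed by a per-step affine projection to two classes with softmax
cross-entropy. Supports full-bidirectional inference and a *causal* mode
in which the backward direction is restarted inside each lookahead block
(so a decision for step t never consumes input beyond its own block).

Shapes follow the (T, B, D) convention: time, batch, features.
Gate order in the fused weight matrices is [input, forget, cell, output].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class LayerParams:
    W: np.ndarray  # (D, 4H)
    U: np.ndarray  # (H, 4H)
    b: np.ndarray  # (4H,)


@dataclass
class NetParams:
    layers: list[tuple[LayerParams, LayerParams]]  # (forward, backward) pairs
    Wo: np.ndarray  # (2H_last, n_classes)
    bo: np.ndarray  # (n_classes,)

    def flat(self) -> list[np.ndarray]:
        out = []
        for fwd, bwd in self.layers:
            out += [fwd.W, fwd.U, fwd.b, bwd.W, bwd.U, bwd.b]
        out += [self.Wo, self.bo]
        return out


def init_params(
    input_dim: int, hidden_sizes, n_classes: int, rng: np.random.Generator
) -> NetParams:
    def glorot(fan_in, fan_out):
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, size=(fan_in, fan_out))

    layers = []
    d = input_dim
    for h in hidden_sizes:
        pair = []
        for _ in range(2):
            b = np.zeros(4 * h)
            b[h:2 * h] = 1.0  # forget-gate bias
            pair.append(LayerParams(glorot(d, 4 * h), glorot(h, 4 * h), b))
        layers.append(tuple(pair))
        d = 2 * h
    return NetParams(layers, glorot(d, n_classes), np.zeros(n_classes))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def lstm_forward(x: np.ndarray, p: LayerParams, h0=None, c0=None):
    """Plain left-to-right pass. Returns (h_all, cache)."""
    T, B, _ = x.shape
    H = p.U.shape[0]
    h = np.zeros((B, H)) if h0 is None else h0
    c = np.zeros((B, H)) if c0 is None else c0
    hs = np.empty((T, B, H))
    cache = {
        "x": x, "i": np.empty((T, B, H)), "f": np.empty((T, B, H)),
        "g": np.empty((T, B, H)), "o": np.empty((T, B, H)),
        "c": np.empty((T, B, H)), "tc": np.empty((T, B, H)),
        "h_prev": np.empty((T, B, H)), "c_prev": np.empty((T, B, H)),
    }
    for t in range(T):
        z = x[t] @ p.W + h @ p.U + p.b
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H])
        o = _sigmoid(z[:, 3 * H:])
        cache["h_prev"][t] = h
        cache["c_prev"][t] = c
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        hs[t] = h
        for k, v in (("i", i), ("f", f), ("g", g), ("o", o), ("c", c), ("tc", tc)):
            cache[k][t] = v
    return hs, cache, h, c


def lstm_backward(dh_all: np.ndarray, cache, p: LayerParams):
    """Backprop through time. Returns (dx, dW, dU, db)."""
    T, B, H = dh_all.shape
    x = cache["x"]
    dx = np.empty_like(x)
    dW = np.zeros_like(p.W)
    dU = np.zeros_like(p.U)
    db = np.zeros_like(p.b)
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        i, f, g, o = cache["i"][t], cache["f"][t], cache["g"][t], cache["o"][t]
        tc = cache["tc"][t]
        dh = dh_all[t] + dh_next
        do = dh * tc
        dc = dc_next + dh * o * (1.0 - tc * tc)
        di = dc * g
        dg = dc * i
        df = dc * cache["c_prev"][t]
        dz = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
            axis=1,
        )
        dW += x[t].T @ dz
        dU += cache["h_prev"][t].T @ dz
        db += dz.sum(axis=0)
        dx[t] = dz @ p.W.T
        dh_next = dz @ p.U.T
        dc_next = dc * f
    return dx, dW, dU, db


def _blockwise_reverse_forward(x: np.ndarray, p: LayerParams, block: int):
    """Backward direction restarted at every ``block`` steps (causal mode).

    Each length-``block`` slice of the sequence is processed right-to-left
    from a zero state, so outputs at step t use inputs from t's own block
    only, never from later blocks. T must be a multiple of ``block``.
    """
    T, B, D = x.shape
    if T % block:
        raise ValueError(f"sequence length {T} not a multiple of block {block}")
    nb = T // block
    # (T,B,D) -> (nb, block, B, D) -> flip in-block time -> (block, nb*B, D)
    xb = x.reshape(nb, block, B, D)[:, ::-1]
    xb = np.ascontiguousarray(xb.transpose(1, 0, 2, 3)).reshape(block, nb * B, D)
    hs, _, _, _ = lstm_forward(xb, p)
    H = p.U.shape[0]
    hs = hs.reshape(block, nb, B, H).transpose(1, 0, 2, 3)[:, ::-1]
    return hs.reshape(T, B, H)


def bilstm_apply(
    params: NetParams, x: np.ndarray, causal_block: int | None = None
) -> np.ndarray:
    """Forward pass to per-step class probabilities, shape (T, B, n_classes).

    ``causal_block=None`` gives the full bidirectional pass; an integer
    restarts the backward direction every that many steps (causal mode).
    """
    h = x
    for fwd, bwd in params.layers:
        hf, _, _, _ = lstm_forward(h, fwd)
        if causal_block is None:
            hb, _, _, _ = lstm_forward(h[::-1], bwd)
            hb = hb[::-1]
        else:
            hb = _blockwise_reverse_forward(h, bwd, causal_block)
        h = np.concatenate([hf, hb], axis=2)
    logits = h @ params.Wo + params.bo
    return softmax(logits)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def loss_and_grads(
    params: NetParams, x: np.ndarray, y: np.ndarray
) -> tuple[float, list[np.ndarray]]:
    """Mean per-step cross-entropy and gradients for every parameter.

    x: (T, B, D); y: (T, B) integer class labels.
    """
    T, B, _ = x.shape
    h = x
    layer_caches = []
    for fwd, bwd in params.layers:
        hf, cf, _, _ = lstm_forward(h, fwd)
        hb_r, cb, _, _ = lstm_forward(h[::-1], bwd)
        hb = hb_r[::-1]
        layer_caches.append((cf, cb, h.shape[2]))
        h = np.concatenate([hf, hb], axis=2)

    logits = h @ params.Wo + params.bo
    probs = softmax(logits)
    n = T * B
    idx_t, idx_b = np.meshgrid(np.arange(T), np.arange(B), indexing="ij")
    p_true = probs[idx_t, idx_b, y]
    loss = float(-np.log(np.clip(p_true, 1e-12, None)).mean())

    dlogits = probs.copy()
    dlogits[idx_t, idx_b, y] -= 1.0
    dlogits /= n
    dWo = np.tensordot(h, dlogits, axes=([0, 1], [0, 1]))
    dbo = dlogits.sum(axis=(0, 1))
    dh = dlogits @ params.Wo.T

    grads_rev: list[np.ndarray] = []
    for (fwd, bwd), (cf, cb, d_in) in zip(
        reversed(params.layers), reversed(layer_caches)
    ):
        H = fwd.U.shape[0]
        dhf = dh[:, :, :H]
        dhb = dh[:, :, H:]
        dxf, dWf, dUf, dbf = lstm_backward(dhf, cf, fwd)
        dxb_r, dWb, dUb, dbb = lstm_backward(dhb[::-1], cb, bwd)
        dh = dxf + dxb_r[::-1]
        grads_rev += [dbb, dUb, dWb, dbf, dUf, dWf]
    grads = grads_rev[::-1] + [dWo, dbo]
    return loss, grads


class Adam:
    def __init__(self, shapes, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
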