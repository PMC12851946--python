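"""Attention-based multiple-instance-learning network in plain numpy.

A small 3-block CNN encodes each tile; a gated attention module (tanh *
sigmoid gate, single head) produces softmax-normalized tile weights; the
slide embedding is the attention-weighted sum of tile embeddings and a
linear head yields 3-class logits.  Forward and backward passes are written
out explicitly, which keeps the model dependency-free and makes the
Grad-CAM gradients exact.

Data layout is NHWC float32.  All randomness flows through a seeded
``numpy`` generator, so training is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# ---------------------------------------------------------------------------
# primitive layers


def _im2col(x: np.ndarray, k: int = 3) -> np.ndarray:
    """(N,H,W,C) -> (N,H,W,k*k*C) patches with same-padding for odd k."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    # win: (N, H, W, C, k, k) -> (N, H, W, k, k, C)
    win = win.transpose(0, 1, 2, 4, 5, 3)
    n, h, w = x.shape[0], x.shape[1], x.shape[2]
    return np.ascontiguousarray(win).reshape(n, h, w, k * k * x.shape[3])


class Conv3x3:
    """3x3 stride-1 same-padding convolution."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (9 * c_in))
        self.W = (rng.normal(0, scale, size=(9 * c_in, c_out))).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.c_in, self.c_out = c_in, c_out

    def forward(self, x):
        self._cols = _im2col(x, 3)
        return self._cols @ self.W + self.b

    def backward(self, dout):
        n, h, w, _ = dout.shape
        cols = self._cols.reshape(-1, 9 * self.c_in)
        dflat = dout.reshape(-1, self.c_out)
        self.dW = cols.T @ dflat
        self.db = dflat.sum(axis=0)
        # input gradient: correlate dout with the 180-degree-rotated kernels
        Wk = self.W.reshape(3, 3, self.c_in, self.c_out)
        Wrot = Wk[::-1, ::-1].transpose(0, 1, 3, 2).reshape(9 * self.c_out, self.c_in)
        return _im2col(dout, 3) @ Wrot

    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


class ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2:
    """2x2 max pooling, stride 2 (inputs must have even H, W)."""

    def forward(self, x):
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        self._x_shape = x.shape
        self._mask = xr == out[:, :, None, :, None, :]
        return out

    def backward(self, dout):
        n, h, w, c = self._x_shape
        d = self._mask * dout[:, :, None, :, None, :]
        return d.reshape(n, h, w, c)


# ---------------------------------------------------------------------------
# model


@dataclass
class MILConfig:
    tile_px: int = 64
    channels: tuple[int, int, int] = (8, 16, 32)
    attention_width: int = 32
    n_classes: int = 3
    class_weights: tuple[float, ...] | None = None  # None -> inverse frequency
    learning_rate: float = 1e-3
    epochs: int = 14
    augment: bool = True
    seed: int = 0
    test_fraction: float = 1.0 / 3.0


class AttentionMILModel:
    """Encoder + gated attention pooling + linear 3-class head."""

    def __init__(self, config: MILConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c1, c2, c3 = config.channels
        self.conv1 = Conv3x3(3, c1, rng)
        self.conv2 = Conv3x3(c1, c2, rng)
        self.conv3 = Conv3x3(c2, c3, rng)
        self.relu1, self.relu2, self.relu3 = ReLU(), ReLU(), ReLU()
        self.pool1, self.pool2 = MaxPool2(), MaxPool2()
        d, a = c3, config.attention_width
        self.Va = (rng.normal(0, 1 / np.sqrt(d), (d, a))).astype(np.float32)
        self.Ua = (rng.normal(0, 1 / np.sqrt(d), (d, a))).astype(np.float32)
        self.wa = (rng.normal(0, 1 / np.sqrt(a), (a,))).astype(np.float32)
        self.Wc = (rng.normal(0, 1 / np.sqrt(d), (d, config.n_classes))).astype(np.float32)
        self.bc = np.zeros(config.n_classes, dtype=np.float32)
        self.trained = False
        self._adam_state: dict = {}
        self._adam_t = 0

    # -- encoder ------------------------------------------------------------
    def encode(self, tiles: np.ndarray) -> np.ndarray:
        """Tiles (N, T, T, 3) in [0, 1] float -> embeddings (N, D)."""
        a1 = self.pool1.forward(self.relu1.forward(self.conv1.forward(tiles)))
        a2 = self.pool2.forward(self.relu2.forward(self.conv2.forward(a1)))
        self._a3 = self.relu3.forward(self.conv3.forward(a2))
        return self._a3.mean(axis=(1, 2))

    def _encoder_backward(self, dh):
        n, hh, ww, c = self._a3.shape
        da3 = np.broadcast_to(dh[:, None, None, :], self._a3.shape) / (hh * ww)
        d = self.conv3.backward(self.relu3.backward(da3))
        d = self.conv2.backward(self.relu2.backward(self.pool2.backward(d)))
        self.conv1.backward(self.relu1.backward(self.pool1.backward(d)))

    # -- attention pooling ----------------------------------------------------
    def attention_pool(self, h: np.ndarray):
        """Embeddings (N, D) -> (slide embedding (D,), weights (N,))."""
        self._h = h
        self._u = np.tanh(h @ self.Va)
        self._g = 1.0 / (1.0 + np.exp(-(h @ self.Ua)))
        score = (self._u * self._g) @ self.wa
        score = score - score.max()
        e = np.exp(score)
        self._a = e / e.sum()
        return self._a @ h, self._a

    def _attention_backward(self, dz, da_extra=None):
        """Gradient wrt embeddings given dz (D,) and optional d(weights)."""
        h, a, u, g = self._h, self._a, self._u, self._g
        dh = a[:, None] * dz[None, :]
        da = h @ dz
        if da_extra is not None:
            da = da + da_extra
        dscore = a * (da - float(a @ da))
        dug = dscore[:, None] * self.wa[None, :]
        self.dwa = (u * g).T @ dscore
        du = dug * g
        dg = dug * u
        dpre_u = du * (1.0 - u**2)
        dpre_g = dg * g * (1.0 - g)
        self.dVa = h.T @ dpre_u
        self.dUa = h.T @ dpre_g
        dh += dpre_u @ self.Va.T + dpre_g @ self.Ua.T
        return dh

    # -- full bag forward/backward -------------------------------------------
    def forward_bag(self, tiles: np.ndarray):
        h = self.encode(tiles)
        z, a = self.attention_pool(h)
        logits = z @ self.Wc + self.bc
        self._z = z
        return logits, a

    def backward_bag(self, dlogits: np.ndarray):
        self.dWc = np.outer(self._z, dlogits)
        self.dbc = dlogits
        dz = self.Wc @ dlogits
        dh = self._attention_backward(dz)
        self._encoder_backward(dh)

    def _params(self):
        out = []
        for conv, name in ((self.conv1, "c1"), (self.conv2, "c2"), (self.conv3, "c3")):
            out.append((f"{name}.W", conv, "W", "dW"))
            out.append((f"{name}.b", conv, "b", "db"))
        for pname in ("Va", "Ua", "wa", "Wc", "bc"):
            out.append((pname, self, pname, "d" + pname))
        return out

    def adam_step(self, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        for key, obj, pname, gname in self._params():
            p = getattr(obj, pname)
            grad = getattr(obj, gname).astype(np.float32)
            m, v = self._adam_state.get(key, (np.zeros_like(p), np.zeros_like(p)))
            m = beta1 * m + (1 - beta1) * grad
            v = beta2 * v + (1 - beta2) * grad * grad
            self._adam_state[key] = (m, v)
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            setattr(obj, pname, p - lr * mhat / (np.sqrt(vhat) + eps))

    def weights_digest(self) -> str:
        import hashlib

        hsh = hashlib.sha256()
        for _, obj, pname, _ in self._params():
            hsh.update(np.ascontiguousarray(getattr(obj, pname)).tobytes())
        return hsh.hexdigest()
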