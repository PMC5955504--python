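"""Minimal CNN layers with explicit backpropagation, NumPy only.

Tensors are NHWC float32.  Each layer caches what its backward pass needs
only when ``training=True``, so inference at full 208x208 scale stays within
a small memory footprint.  Convolution is implemented by stacking the k*k
shifted views of the (padded) input into a column matrix and calling one
BLAS matmul — the fastest pure-NumPy route for 3x3 kernels.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D",
    "LeakyReLU",
    "MaxPool2",
    "Upsample2",
    "ChannelDropout",
]


def init_weights(shape: tuple[int, int], fan_in: int, fan_out: int, scheme: str,
                 rng: np.random.Generator) -> np.ndarray:
    if scheme == "lecun_uniform":
        limit = np.sqrt(3.0 / fan_in)
        w = rng.uniform(-limit, limit, size=shape)
    elif scheme == "xavier_normal":
        std = np.sqrt(2.0 / (fan_in + fan_out))
        w = rng.normal(0.0, std, size=shape)
    else:
        raise ValueError(f"unknown init scheme {scheme!r}")
    return w.astype(np.float32)


class Conv2D:
    """k x k convolution, stride 1, zero ('same') or no ('valid') padding."""

    def __init__(self, cin: int, cout: int, k: int = 3, padding: str = "same",
                 init: str = "lecun_uniform", rng: np.random.Generator | None = None,
                 name: str = ""):
        if padding not in ("same", "valid"):
            raise ValueError("padding must be 'same' or 'valid'")
        rng = rng or np.random.default_rng()
        self.cin, self.cout, self.k, self.padding = cin, cout, k, padding
        self.name = name
        fan_in = k * k * cin
        fan_out = k * k * cout
        self.W = init_weights((fan_in, cout), fan_in, fan_out, init, rng)
        self.b = np.zeros(cout, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._cache = None

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]

    def _cols(self, xp: np.ndarray, ho: int, wo: int) -> np.ndarray:
        n, _, _, c = xp.shape
        k = self.k
        cols = np.empty((n, ho, wo, k * k * c), dtype=np.float32)
        idx = 0
        for i in range(k):
            for j in range(k):
                cols[..., idx * c : (idx + 1) * c] = xp[:, i : i + ho, j : j + wo, :]
                idx += 1
        return cols

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        p = self.k // 2 if self.padding == "same" else 0
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        n, hp, wp, c = xp.shape
        ho, wo = hp - self.k + 1, wp - self.k + 1
        if ho < 1 or wo < 1:
            raise ValueError(f"layer {self.name or 'conv'}: grid {x.shape[1:3]} too "
                             f"small for a {self.k}x{self.k} valid convolution")
        cols = self._cols(xp, ho, wo)
        y = cols.reshape(-1, self.k * self.k * c) @ self.W + self.b
        y = y.reshape(n, ho, wo, self.cout)
        if training:
            self._cache = (cols, xp.shape, p)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xp_shape, p = self._cache
        n, ho, wo, cout = dy.shape
        c = self.cin
        dy_flat = np.ascontiguousarray(dy, dtype=np.float32).reshape(-1, cout)
        cols_flat = cols.reshape(-1, self.k * self.k * c)
        self.gW[...] = cols_flat.T @ dy_flat
        self.gb[...] = dy_flat.sum(axis=0)
        dcols = (dy_flat @ self.W.T).reshape(n, ho, wo, self.k * self.k * c)
        dxp = np.zeros(xp_shape, dtype=np.float32)
        idx = 0
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, i : i + ho, j : j + wo, :] += dcols[..., idx * c : (idx + 1) * c]
                idx += 1
        self._cache = None
        if p:
            return dxp[:, p:-p, p:-p, :]
        return dxp


class LeakyReLU:
    """max(x, slope*x); the paper-style nonlinearity after every convolution."""

    def __init__(self, slope: float = 0.01):
        self.slope = slope
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        pos = x > 0
        y = np.where(pos, x, self.slope * x)
        if training:
            self._mask = pos
        return y.astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.where(self._mask, dy, self.slope * dy).astype(np.float32)
        self._mask = None
        return dx


class MaxPool2:
    """2x2 max pooling, stride 2; requires an even grid."""

    def __init__(self, name: str = ""):
        self.name = name
        self._cache = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"layer {self.name or 'pool'}: grid {h}x{w} is not "
                             "divisible by 2 — non-integral pooled grid")
        xr = (
            x.reshape(n, h // 2, 2, w // 2, 2, c)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(n, h // 2, w // 2, c, 4)
        )
        idx = np.argmax(xr, axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if training:
            self._cache = (idx, (n, h, w, c))
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, (n, h, w, c) = self._cache
        dxr = np.zeros((n, h // 2, w // 2, c, 4), dtype=np.float32)
        np.put_along_axis(dxr, idx[..., None], dy[..., None].astype(np.float32), axis=-1)
        dx = (
            dxr.reshape(n, h // 2, w // 2, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, h, w, c)
        )
        self._cache = None
        return dx


class Upsample2:
    """2x nearest-neighbor upsampling (resize step of resize-then-convolve)."""

    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return np.ascontiguousarray(x.repeat(2, axis=1).repeat(2, axis=2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h2, w2, c = dy.shape
        return (
            dy.reshape(n, h2 // 2, 2, w2 // 2, 2, c).sum(axis=(2, 4)).astype(np.float32)
        )


class ChannelDropout:
    """Drops whole feature maps (filters) with probability ``rate`` in training.

    Inverted dropout: survivors are scaled by 1/(1-rate) so inference is the
    identity.
    """

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng()
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0.0:
            return x
        n, _, _, c = x.shape
        keep = (self.rng.random((n, 1, 1, c)) >= self.rate).astype(np.float32)
        keep /= 1.0 - self.rate
        self._mask = keep
        return x * keep

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        dx = dy * self._mask
        self._mask = None
        return dx
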