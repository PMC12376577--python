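"""Minimal CPU neural-network primitives (numpy, manual backprop).

Layers operate on NCHW float32 tensors and implement ``forward`` /
``backward`` pairs with explicit caches; convolutions lower to im2col
matrix products so the heavy lifting runs in BLAS.  Parameters are plain
``Param`` objects (data + accumulated gradient) collected by the models
and updated by the Adam optimizer in :mod:`strain2scar.nn.optim`.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.name = name


def _conv_forward(x: np.ndarray, W: np.ndarray, pad):
    """Same-size 2-D correlation via im2col; returns (out, cols) where cols
    is the flattened patch matrix cached for the weight gradient."""
    (pt, pb), (pl, pr) = pad
    xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    kh, kw = W.shape[2], W.shape[3]
    cols = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    n, c, ho, wo = cols.shape[:4]
    cols2 = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)
                                 ).reshape(n * ho * wo, c * kh * kw)
    out = cols2 @ W.reshape(W.shape[0], -1).T
    out = out.reshape(n, ho, wo, W.shape[0]).transpose(0, 3, 1, 2)
    return np.ascontiguousarray(out), cols2


class Conv2d:
    """2-D convolution with bias, stride 1, shape-preserving zero padding.

    Even kernels pad asymmetrically ((k-1)//2 before, the rest after), so
    a 10x10 kernel also maps H x W onto H x W.
    """

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 name: str = "conv"):
        pt = (k - 1) // 2
        self.pad = ((pt, k - 1 - pt), (pt, k - 1 - pt))
        std = np.sqrt(2.0 / (cin * k * k))
        self.W = Param(rng.normal(0.0, std, (cout, cin, k, k)), f"{name}.W")
        self.b = Param(np.zeros(cout), f"{name}.b")
        self.k = k
        self._cache = None

    def parameters(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        out, cols2 = _conv_forward(x, self.W.data, self.pad)
        self._cache = (x.shape, cols2)
        return out + self.b.data[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x_shape, cols2 = self._cache
        n, cout, ho, wo = dy.shape
        dy2 = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, cout)
        self.W.grad += (dy2.T @ cols2).reshape(self.W.data.shape)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        # dx: full correlation of dy with the flipped, channel-swapped kernel
        W_flip = np.ascontiguousarray(
            self.W.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
        (pt, pb), (pl, pr) = self.pad
        back_pad = ((pb, pt), (pr, pl))
        dx, _ = _conv_forward(dy, W_flip, back_pad)
        return dx


class ConvTranspose2d:
    """2x2 transposed convolution with stride 2 (non-overlapping up-sampling)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 name: str = "upconv"):
        std = np.sqrt(2.0 / (cin * 4))
        self.W = Param(rng.normal(0.0, std, (cin, cout, 2, 2)), f"{name}.W")
        self.b = Param(np.zeros(cout), f"{name}.b")
        self._x = None

    def parameters(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        n, c, h, w = x.shape
        t = np.tensordot(x, self.W.data, axes=([1], [0]))  # (N,H,W,O,2,2)
        out = t.transpose(0, 3, 1, 4, 2, 5).reshape(n, self.W.data.shape[1],
                                                    2 * h, 2 * w)
        return np.ascontiguousarray(out) + self.b.data[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        n, c, h, w = x.shape
        o = dy.shape[1]
        blocks = np.ascontiguousarray(
            dy.reshape(n, o, h, 2, w, 2).transpose(0, 2, 4, 1, 3, 5))
        self.W.grad += np.tensordot(x, blocks, axes=([0, 2, 3], [0, 1, 2]))
        self.b.grad += dy.sum(axis=(0, 2, 3))
        dx = np.tensordot(blocks, self.W.data, axes=([3, 4, 5], [1, 2, 3]))
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))


class MaxPool2d:
    """2x2 max pooling, stride 2."""

    def __init__(self):
        self._cache = None

    def parameters(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        r = np.ascontiguousarray(r).reshape(n, c, h // 2, w // 2, 4)
        idx = r.argmax(axis=-1)
        out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, idx)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        (n, c, h, w), idx = self._cache
        flat = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(flat, idx[..., None], dy[..., None], axis=-1)
        dx = flat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(dx).reshape(n, c, h, w)


class ReLU:
    def __init__(self):
        self._mask = None

    def parameters(self):
        return []

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(x.dtype)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0).astype(dy.dtype)


class LeakyReLU:
    def __init__(self, slope: float = 0.01):
        self.slope = slope
        self._mask = None

    def parameters(self):
        return []

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x).astype(x.dtype)

    def backward(self, dy):
        return np.where(self._mask, dy, self.slope * dy).astype(dy.dtype)


class Sigmoid:
    def __init__(self):
        self._y = None

    def parameters(self):
        return []

    def forward(self, x):
        y = 1.0 / (1.0 + np.exp(-x.astype(np.float64)))
        self._y = y.astype(x.dtype)
        return self._y

    def backward(self, dy):
        y = self._y
        return (dy * y * (1.0 - y)).astype(dy.dtype)


class ConvBlock:
    """Two 3x3 convolution + ReLU pairs, the standard UNet block."""

    def __init__(self, cin: int, cout: int, rng, name: str):
        self.conv1 = Conv2d(cin, cout, 3, rng, f"{name}.conv1")
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, rng, f"{name}.conv2")
        self.relu2 = ReLU()

    def parameters(self):
        return self.conv1.parameters() + self.conv2.parameters()

    def forward(self, x):
        return self.relu2.forward(self.conv2.forward(
            self.relu1.forward(self.conv1.forward(x))))

    def backward(self, dy):
        return self.conv1.backward(self.relu1.backward(
            self.conv2.backward(self.relu2.backward(dy))))


def concat_channels(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.concatenate([a, b], axis=1)


def split_channels(d: np.ndarray, c_first: int):
    return d[:, :c_first], d[:, c_first:]
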