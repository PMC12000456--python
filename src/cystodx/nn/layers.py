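"""Minimal feed-forward layer engine with explicit backprop.

All layers operate on NHWC float32 batches. Every layer caches what its
backward pass needs during ``forward`` and exposes trainable arrays through
``params``/``grads`` dicts so the optimizer can update them in place.
ReLU layers support a *guided* backward mode (gradient passes only where the
forward pre-activation and the incoming gradient are both positive), which is
what guided backpropagation saliency requires.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base class: stateless unless a subclass declares parameters."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.name: str = self.__class__.__name__

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2D(Layer):
    """Stride-1 2-D convolution (cross-correlation), 'valid' or 'same' padding.

    Weights are He-initialized: std = sqrt(2 / fan_in), the standard choice
    for ReLU stacks trained from scratch.
    """

    def __init__(self, in_ch: int, out_ch: int, ksize: int, padding: str = "valid",
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if padding not in ("valid", "same"):
            raise ValueError(f"unknown padding {padding!r}")
        if padding == "same" and ksize % 2 == 0:
            raise ValueError("'same' padding requires an odd kernel size")
        rng = rng or np.random.default_rng(0)
        self.ksize = ksize
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.padding = padding
        fan_in = ksize * ksize * in_ch
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, out_ch))
        self.params = {"w": w.astype(np.float32), "b": np.zeros(out_ch, np.float32)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._cols: np.ndarray | None = None
        self._xshape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.ksize
        if self.padding == "same":
            p = k // 2
            x = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        n, h, w, c = x.shape
        if h < k or w < k:
            raise ValueError(f"input {h}x{w} smaller than kernel {k}")
        # (n, oh, ow, c, k, k) view -> (n*oh*ow, k*k*c) matrix
        win = sliding_window_view(x, (k, k), axis=(1, 2))
        oh, ow = win.shape[1], win.shape[2]
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * oh * ow, k * k * c)
        self._cols = cols
        self._xshape = x.shape
        out = cols @ self.params["w"] + self.params["b"]
        return out.reshape(n, oh, ow, self.out_ch)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        k = self.ksize
        n, oh, ow, f = grad.shape
        gflat = grad.reshape(n * oh * ow, f)
        self.grads["w"][...] = self._cols.T @ gflat
        self.grads["b"][...] = gflat.sum(axis=0)
        dcols = (gflat @ self.params["w"].T).reshape(n, oh, ow, k, k, self.in_ch)
        dx = np.zeros(self._xshape, np.float32)
        for i in range(k):
            for j in range(k):
                dx[:, i:i + oh, j:j + ow, :] += dcols[:, :, :, i, j, :]
        if self.padding == "same":
            p = k // 2
            dx = dx[:, p:-p, p:-p, :]
        return dx


class ReLU(Layer):
    """Elementwise max(z, 0); supports guided backprop gating."""

    def __init__(self) -> None:
        super().__init__()
        self.guided = False
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = grad * self._mask
        if self.guided:
            g = np.where(g > 0, g, 0.0)
        return g.astype(np.float32)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2. Requires even spatial dims."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2 needs even dims, got {h}x{w}")
        oh, ow = h // 2, w // 2
        xr = x.reshape(n, oh, 2, ow, 2, c).transpose(0, 1, 3, 2, 4, 5)
        xr = xr.reshape(n, oh, ow, 4, c)
        self._argmax = xr.argmax(axis=3)
        self._inshape = x.shape
        return xr.max(axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, oh, ow, c = grad.shape
        scattered = np.zeros((n, oh, ow, 4, c), np.float32)
        idx = np.indices((n, oh, ow, c))
        scattered[idx[0], idx[1], idx[2], self._argmax, idx[3]] = grad
        dx = scattered.reshape(n, oh, ow, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        return dx.reshape(self._inshape).astype(np.float32)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._inshape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._inshape)


class GlobalAvgPool(Layer):
    """Spatial mean per feature map: (N,H,W,C) -> (N,C)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._inshape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, c = self._inshape
        g = grad[:, None, None, :] / (h * w)
        return np.broadcast_to(g, self._inshape).astype(np.float32)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.params = {"w": w.astype(np.float32), "b": np.zeros(n_out, np.float32)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads["w"][...] = self._x.T @ grad
        self.grads["b"][...] = grad.sum(axis=0)
        return (grad @ self.params["w"].T).astype(np.float32)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))
        return self._y.astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return (grad * self._y * (1.0 - self._y)).astype(np.float32)


class Upsample2(Layer):
    """Nearest-neighbour 2x spatial upsampling (used by the GAN generator)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, c = grad.shape
        g = grad.reshape(n, h // 2, 2, w // 2, 2, c)
        return g.sum(axis=(2, 4)).astype(np.float32)
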