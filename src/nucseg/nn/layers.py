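"""CNN building blocks in NumPy (NHWC, float32).

Convolutions use im2col + BLAS matmul, which is the fastest route
available without a deep-learning framework. The transposed 2x2
stride-2 convolution exploits that kernel == stride: output windows do
not overlap, so forward and backward are pure einsum reshapes.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base: parameterless layers leave ``params``/``grads`` empty."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def he_uniform(shape: tuple[int, ...], fan_in: int, rng: np.random.Generator) -> np.ndarray:
    """He-uniform init, the standard choice under ReLU activations."""
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv2D(Layer):
    """kh x kw convolution, 'same' zero padding, stride 1, with bias.

    Implemented as shift-and-accumulate: one (B*H*W, Cin) x (Cin, Cout)
    matmul per kernel offset. For the narrow channel counts of a
    lightweight U-Net this is far cheaper in memory traffic than
    materializing a full im2col matrix.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, activation: str | None = "relu"):
        super().__init__()
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        fan_in = kernel * kernel * c_in
        self.params["W"] = he_uniform((fan_in, c_out), fan_in, rng)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)
        self.activation = activation
        self._xp: np.ndarray | None = None
        self._relu_mask: np.ndarray | None = None

    @property
    def pad(self) -> int:
        return (self.kernel - 1) // 2

    def _w_at(self, i: int, j: int) -> np.ndarray:
        # rows of W are flattened (kh, kw, cin)
        k, c = self.kernel, self.c_in
        return self.params["W"][(i * k + j) * c:(i * k + j + 1) * c, :]

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, h, w, c = x.shape
        assert c == self.c_in, (c, self.c_in)
        k, p = self.kernel, self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        self._xp = xp
        self._shape = (b, h, w)
        if k == 1:
            y = x.reshape(-1, c) @ self.params["W"]
            y = y.reshape(b, h, w, self.c_out)
        else:
            y = np.zeros((b, h, w, self.c_out), dtype=x.dtype)
            flat = y.reshape(-1, self.c_out)
            for i in range(k):
                for j in range(k):
                    patch = np.ascontiguousarray(
                        xp[:, i:i + h, j:j + w, :]).reshape(-1, c)
                    flat += patch @ self._w_at(i, j)
        y += self.params["b"]
        if self.activation == "relu":
            self._relu_mask = y > 0
            y = y * self._relu_mask
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, h, w = self._shape
        k, p, c = self.kernel, self.pad, self.c_in
        if self.activation == "relu":
            dy = dy * self._relu_mask
        dy_flat = np.ascontiguousarray(dy).reshape(-1, self.c_out)
        xp = self._xp
        dW = np.empty_like(self.params["W"])
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                patch = np.ascontiguousarray(
                    xp[:, i:i + h, j:j + w, :]).reshape(-1, c)
                dW[(i * k + j) * c:(i * k + j + 1) * c, :] = patch.T @ dy_flat
                dxp[:, i:i + h, j:j + w, :] += (
                    dy_flat @ self._w_at(i, j).T).reshape(b, h, w, c)
        self.grads["W"] = dW
        self.grads["b"] = dy_flat.sum(axis=0)
        self._xp = None
        return dxp[:, p:p + h, p:p + w, :] if p else dxp


class MaxPool2x2(Layer):
    """2x2 max pooling, stride 2; requires even spatial dims."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, h, w, c = x.shape
        assert h % 2 == 0 and w % 2 == 0, (h, w)
        # (B, H/2, W/2, C, 4): the 4 pixels of each window
        win = x.reshape(b, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        win = win.reshape(b, h // 2, w // 2, c, 4)
        self._argmax = win.argmax(axis=-1)
        self._shape = x.shape
        return win.max(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, h, w, c = self._shape
        dwin = np.zeros((b, h // 2, w // 2, c, 4), dtype=dy.dtype)
        np.put_along_axis(dwin, self._argmax[..., None], dy[..., None], axis=-1)
        dx = dwin.reshape(b, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return dx.reshape(b, h, w, c)


class ConvTranspose2x2(Layer):
    """2x2 transposed convolution with stride 2 (spatial doubling).

    Kernel equals stride, so each input pixel paints a disjoint 2x2
    output block — no overlap-add is needed.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.params["W"] = he_uniform((2, 2, c_in, c_out), c_in, rng)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, h, w, c = x.shape
        self._x = x
        y = np.einsum("bhwc,ijck->bhiwjk", x, self.params["W"], optimize=True)
        return y.reshape(b, 2 * h, 2 * w, self.c_out) + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, h2, w2, k = dy.shape
        dyr = dy.reshape(b, h2 // 2, 2, w2 // 2, 2, k)
        self.grads["W"] = np.einsum("bhwc,bhiwjk->ijck", self._x, dyr, optimize=True)
        self.grads["b"] = dy.sum(axis=(0, 1, 2))
        dx = np.einsum("bhiwjk,ijck->bhwc", dyr, self.params["W"], optimize=True)
        self._x = None
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; identity when ``training`` is False."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0,1), got {rate}")
        self.rate = rate
        self.training = False
        self.rng = np.random.default_rng(0)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax."""
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)
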