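"""Minimal CNN engine in NumPy: the layers the fine-stage network needs.

Data layout is channels-last, (batch, height, width, channels). Convolutions
are 3×3 with 'same' padding, implemented by patch extraction (im2col) and a
single matmul; the depthwise-separable variant factors into a per-channel
spatial convolution (no bias) followed by a 1×1 pointwise convolution with
biases, the factorization whose trainable-parameter count is
k·k·c + c·N + N against k·k·c·N + N for the standard layer.

Gradients are exact (verified by finite differences in the test suite);
optimization is Adam with softmax cross-entropy.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "SeparableConv2D", "Conv2D", "ReLU", "Dropout", "MaxPool2D",
    "ZeroPadWidth", "Flatten", "Dense", "Network", "Adam",
    "softmax", "cross_entropy",
]


def _im2col(x: np.ndarray, k: int = 3) -> np.ndarray:
    """(B,H,W,C) → (B,H,W,k²,C) patches, 'same' zero padding."""
    pad = k // 2
    B, H, W, C = x.shape
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    cols = np.empty((B, H, W, k * k, C), dtype=x.dtype)
    idx = 0
    for di in range(k):
        for dj in range(k):
            cols[:, :, :, idx, :] = xp[:, di:di + H, dj:dj + W, :]
            idx += 1
    return cols


def _col2im(dcols: np.ndarray, shape: tuple, k: int = 3) -> np.ndarray:
    pad = k // 2
    B, H, W, C = shape
    dxp = np.zeros((B, H + 2 * pad, W + 2 * pad, C), dtype=dcols.dtype)
    idx = 0
    for di in range(k):
        for dj in range(k):
            dxp[:, di:di + H, dj:dj + W, :] += dcols[:, :, :, idx, :]
            idx += 1
    return dxp[:, pad:pad + H, pad:pad + W, :]


class Layer:
    """Base layer: no parameters, identity shape bookkeeping."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self):
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))


class SeparableConv2D(Layer):
    """Depthwise 3×3 (no bias) + pointwise 1×1 (with bias), 'same' padding."""

    def __init__(self, c_in: int, n_filters: int, k: int = 3,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.k, self.c_in, self.n_filters = k, c_in, n_filters
        wd = rng.standard_normal((k * k, c_in)) * np.sqrt(2.0 / (k * k))
        wp = rng.standard_normal((c_in, n_filters)) * np.sqrt(2.0 / c_in)
        b = np.zeros(n_filters)
        self.params = [wd, wp, b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, train=False):
        wd, wp, b = self.params
        self._xshape = x.shape
        self._cols = _im2col(x, self.k)
        self._dw = np.einsum("bhwtc,tc->bhwc", self._cols, wd)
        B, H, W, C = self._dw.shape
        out = self._dw.reshape(-1, C) @ wp + b
        return out.reshape(B, H, W, self.n_filters)

    def backward(self, dout):
        wd, wp, _ = self.params
        B, H, W, N = dout.shape
        dflat = dout.reshape(-1, N)
        self.grads[2][...] = dflat.sum(axis=0)
        self.grads[1][...] = self._dw.reshape(-1, self.c_in).T @ dflat
        ddw = (dflat @ wp.T).reshape(B, H, W, self.c_in)
        self.grads[0][...] = np.einsum("bhwtc,bhwc->tc", self._cols, ddw)
        dcols = np.einsum("bhwc,tc->bhwtc", ddw, wd)
        return _col2im(dcols, self._xshape, self.k)


class Conv2D(Layer):
    """Standard 3×3 convolution with biases, 'same' padding."""

    def __init__(self, c_in: int, n_filters: int, k: int = 3,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.k, self.c_in, self.n_filters = k, c_in, n_filters
        w = rng.standard_normal((k * k * c_in, n_filters)) * np.sqrt(2.0 / (k * k * c_in))
        self.params = [w, np.zeros(n_filters)]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, train=False):
        w, b = self.params
        self._xshape = x.shape
        B, H, W, C = x.shape
        self._cols = _im2col(x, self.k).reshape(B, H, W, self.k * self.k * C)
        out = self._cols.reshape(-1, self._cols.shape[-1]) @ w + b
        return out.reshape(B, H, W, self.n_filters)

    def backward(self, dout):
        w, _ = self.params
        B, H, W, N = dout.shape
        dflat = dout.reshape(-1, N)
        self.grads[1][...] = dflat.sum(axis=0)
        cols_flat = self._cols.reshape(-1, self._cols.shape[-1])
        self.grads[0][...] = cols_flat.T @ dflat
        dcols = (dflat @ w.T).reshape(B, H, W, self.k * self.k, self.c_in)
        return _col2im(dcols, self._xshape, self.k)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float = 0.5, rng: np.random.Generator | None = None):
        super().__init__()
        self.rate = rate
        self.rng = rng or np.random.default_rng()

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class MaxPool2D(Layer):
    """2×2 max pooling, stride 2; odd trailing rows/columns are dropped."""

    def forward(self, x, train=False):
        B, H, W, C = x.shape
        self._xshape = x.shape
        H2, W2 = H // 2, W // 2
        xc = x[:, :H2 * 2, :W2 * 2, :]
        xr = (xc.reshape(B, H2, 2, W2, 2, C)
                .transpose(0, 1, 3, 5, 2, 4).reshape(B, H2, W2, C, 4))
        self._arg = xr.argmax(axis=-1)
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        B, H, W, C = self._xshape
        H2, W2 = H // 2, W // 2
        dxr = np.zeros((B, H2, W2, C, 4), dtype=dout.dtype)
        np.put_along_axis(dxr, self._arg[..., None], dout[..., None], axis=-1)
        dxc = (dxr.reshape(B, H2, W2, C, 2, 2)
                  .transpose(0, 1, 4, 2, 5, 3).reshape(B, H2 * 2, W2 * 2, C))
        dx = np.zeros(self._xshape, dtype=dout.dtype)
        dx[:, :H2 * 2, :W2 * 2, :] = dxc
        return dx


class ZeroPadWidth(Layer):
    """Zero-pad the width axis by ``pad`` columns on each side."""

    def __init__(self, pad: int = 1):
        super().__init__()
        self.pad = pad

    def forward(self, x, train=False):
        return np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (0, 0)))

    def backward(self, dout):
        return dout[:, :, self.pad:dout.shape[2] - self.pad, :]


class Flatten(Layer):
    def forward(self, x, train=False):
        self._xshape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._xshape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        w = rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in)
        self.params = [w, np.zeros(d_out)]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, dout):
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.params[0].T


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(np.log(probs[np.arange(len(y)), y] + eps)))


class Network:
    """A sequential stack ending in logits; softmax applied by the loss."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    @property
    def params(self) -> list[np.ndarray]:
        return [p for lay in self.layers for p in lay.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for lay in self.layers for g in lay.grads]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for lay in self.layers:
            x = lay.forward(x, train=train)
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, train=False))

    def loss_and_backward(self, x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
        """Softmax cross-entropy forward/backward pass; fills layer grads.

        Returns the batch loss and the number of correct predictions (at
        the pre-update weights).
        """
        probs = softmax(self.forward(x, train=True))
        loss = cross_entropy(probs, y)
        n_correct = int(np.count_nonzero(probs.argmax(axis=1) == y))
        dlogits = probs.copy()
        dlogits[np.arange(len(y)), y] -= 1.0
        dlogits /= len(y)
        dout = dlogits
        for lay in reversed(self.layers):
            dout = lay.backward(dout)
        return loss, n_correct

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights):
            p[...] = w


class Adam:
    """Adam with the customary defaults (lr 1e-3, β₁ 0.9, β₂ 0.999)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
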