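"""Layer primitives with explicit backward passes.

Every layer caches what it needs during ``forward`` and releases the
gradient of its input from ``backward``; parameter gradients accumulate in
``layer.grads`` and are consumed by an optimizer.  Convolutions use
``sliding_window_view`` + ``einsum`` (im2col without the copy), which is the
fastest pure-numpy route at the small spatial sizes this package targets.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable piecewise form
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base class: parameters, gradients, forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k] = np.asarray(v, dtype=self.params[k].dtype)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / max(fan_in, 1))
    return rng.normal(0.0, std, size=shape).astype(DTYPE)


class Conv2d(Layer):
    """3x3 (or any odd k) stride-1 'same' 2D convolution."""

    def __init__(self, cin: int, cout: int, k: int = 3, *, rng: np.random.Generator,
                 bias: bool = True) -> None:
        super().__init__()
        if k % 2 != 1:
            raise ValueError("Conv2d supports odd kernel sizes only")
        self.k, self.pad = k, k // 2
        self.params["W"] = _he_init(rng, (cout, cin, k, k), cin * k * k)
        self.use_bias = bias
        if bias:
            self.params["b"] = np.zeros(cout, dtype=DTYPE)
        for key, v in self.params.items():
            self.grads[key] = np.zeros_like(v)

    def forward(self, x, training=False):
        k, p = self.k, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        self._cols = sliding_window_view(xp, (k, k), axis=(2, 3))  # N,C,H,W,k,k
        y = np.einsum("nchwij,ocij->nohw", self._cols, self.params["W"], optimize=True)
        if self.use_bias:
            y += self.params["b"][None, :, None, None]
        return y.astype(DTYPE, copy=False)

    def backward(self, gy):
        k, p = self.k, self.pad
        self.grads["W"] += np.einsum("nchwij,nohw->ocij", self._cols, gy, optimize=True)
        if self.use_bias:
            self.grads["b"] += gy.sum(axis=(0, 2, 3))
        gyp = np.pad(gy, ((0, 0), (0, 0), (p, p), (p, p)))
        gcols = sliding_window_view(gyp, (k, k), axis=(2, 3))
        Wf = self.params["W"][:, :, ::-1, ::-1]
        gx = np.einsum("nohwij,ocij->nchw", gcols, Wf, optimize=True)
        self._cols = None
        return gx.astype(DTYPE, copy=False)


class ConvTranspose2d(Layer):
    """2x2 stride-2 transposed convolution (learned 2x upsampling)."""

    def __init__(self, cin: int, cout: int, *, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["W"] = _he_init(rng, (cin, cout, 2, 2), cin)
        self.params["b"] = np.zeros(cout, dtype=DTYPE)
        for key, v in self.params.items():
            self.grads[key] = np.zeros_like(v)

    def forward(self, x, training=False):
        self._x = x
        n, _, h, w = x.shape
        cout = self.params["W"].shape[1]
        # y[n,o,2h+a,2w+b] = sum_c x[n,c,h,w] W[c,o,a,b]
        t = np.einsum("nchw,coab->nohawb", x, self.params["W"], optimize=True)
        y = t.reshape(n, cout, 2 * h, 2 * w) + self.params["b"][None, :, None, None]
        return y.astype(DTYPE, copy=False)

    def backward(self, gy):
        n, cout, H2, W2 = gy.shape
        g = gy.reshape(n, cout, H2 // 2, 2, W2 // 2, 2)  # n,o,h,a,w,b
        self.grads["W"] += np.einsum("nchw,nohawb->coab", self._x, g, optimize=True)
        self.grads["b"] += gy.sum(axis=(0, 2, 3))
        gx = np.einsum("nohawb,coab->nchw", g, self.params["W"], optimize=True)
        self._x = None
        return gx.astype(DTYPE, copy=False)


class Conv3d(Layer):
    """3x3x3 stride-1 'same' 3D convolution."""

    def __init__(self, cin: int, cout: int, k: int = 3, *, rng: np.random.Generator,
                 bias: bool = True) -> None:
        super().__init__()
        if k % 2 != 1:
            raise ValueError("Conv3d supports odd kernel sizes only")
        self.k, self.pad = k, k // 2
        self.params["W"] = _he_init(rng, (cout, cin, k, k, k), cin * k ** 3)
        self.use_bias = bias
        if bias:
            self.params["b"] = np.zeros(cout, dtype=DTYPE)
        for key, v in self.params.items():
            self.grads[key] = np.zeros_like(v)

    def forward(self, x, training=False):
        k, p = self.k, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        self._cols = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
        y = np.einsum("ncdhwijk,ocijk->nodhw", self._cols, self.params["W"],
                      optimize=True)
        if self.use_bias:
            y += self.params["b"][None, :, None, None, None]
        return y.astype(DTYPE, copy=False)

    def backward(self, gy):
        k, p = self.k, self.pad
        self.grads["W"] += np.einsum("ncdhwijk,nodhw->ocijk", self._cols, gy,
                                     optimize=True)
        if self.use_bias:
            self.grads["b"] += gy.sum(axis=(0, 2, 3, 4))
        gyp = np.pad(gy, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        gcols = sliding_window_view(gyp, (k, k, k), axis=(2, 3, 4))
        Wf = self.params["W"][:, :, ::-1, ::-1, ::-1]
        gx = np.einsum("nodhwijk,ocijk->ncdhw", gcols, Wf, optimize=True)
        self._cols = None
        return gx.astype(DTYPE, copy=False)


class PointwiseConv3d(Layer):
    """1x1x1 3D convolution: a per-voxel linear map over channels."""

    def __init__(self, cin: int, cout: int, *, rng: np.random.Generator,
                 bias: bool = True) -> None:
        super().__init__()
        self.params["W"] = _he_init(rng, (cout, cin), cin)
        self.use_bias = bias
        if bias:
            self.params["b"] = np.zeros(cout, dtype=DTYPE)
        for key, v in self.params.items():
            self.grads[key] = np.zeros_like(v)

    def forward(self, x, training=False):
        self._x = x
        y = np.einsum("ncdhw,oc->nodhw", x, self.params["W"], optimize=True)
        if self.use_bias:
            y += self.params["b"][None, :, None, None, None]
        return y.astype(DTYPE, copy=False)

    def backward(self, gy):
        self.grads["W"] += np.einsum("ncdhw,nodhw->oc", self._x, gy, optimize=True)
        if self.use_bias:
            self.grads["b"] += gy.sum(axis=(0, 2, 3, 4))
        gx = np.einsum("nodhw,oc->ncdhw", gy, self.params["W"], optimize=True)
        self._x = None
        return gx.astype(DTYPE, copy=False)


class BatchNorm(Layer):
    """Batch normalization over the batch and all spatial axes.

    Works for both 2D (N,C,H,W) and 3D (N,C,D,H,W) inputs.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(channels, dtype=DTYPE)
        self.params["beta"] = np.zeros(channels, dtype=DTYPE)
        for key, v in self.params.items():
            self.grads[key] = np.zeros_like(v)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)

    def _shape(self, x):
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x, training=False):
        sh = self._shape(x)
        axes = (0,) + tuple(range(2, x.ndim))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(DTYPE)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(sh)) * inv.reshape(sh)
        self._cache = (xhat, inv, axes, sh, training)
        y = self.params["gamma"].reshape(sh) * xhat + self.params["beta"].reshape(sh)
        return y.astype(DTYPE, copy=False)

    def backward(self, gy):
        xhat, inv, axes, sh, trained = self._cache
        self.grads["gamma"] += (gy * xhat).sum(axis=axes)
        self.grads["beta"] += gy.sum(axis=axes)
        g = gy * self.params["gamma"].reshape(sh)
        if not trained:
            # running statistics are constants w.r.t. the input
            gx = g * inv.reshape(sh)
            self._cache = None
            return gx.astype(DTYPE, copy=False)
        m = float(np.prod([gy.shape[a] for a in axes]))
        gx = (inv.reshape(sh) / m) * (
            m * g
            - g.sum(axis=axes).reshape(sh)
            - xhat * (g * xhat).sum(axis=axes).reshape(sh)
        )
        self._cache = None
        return gx.astype(DTYPE, copy=False)

    def state_dict(self):
        d = super().state_dict()
        d["running_mean"] = self.running_mean.copy()
        d["running_var"] = self.running_var.copy()
        return d

    def load_state_dict(self, state):
        self.running_mean = np.asarray(state.pop("running_mean"), dtype=DTYPE)
        self.running_var = np.asarray(state.pop("running_var"), dtype=DTYPE)
        super().load_state_dict(state)


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(DTYPE, copy=False)

    def backward(self, gy):
        gx = gy * self._mask
        self._mask = None
        return gx


class Sigmoid(Layer):
    def forward(self, x, training=False):
        self._y = sigmoid(x).astype(DTYPE, copy=False)
        return self._y

    def backward(self, gy):
        gx = gy * self._y * (1.0 - self._y)
        self._y = None
        return gx


def _pool_crop(x, nspatial):
    """Crop trailing odd voxels so every spatial dim is even (floor pooling)."""
    sl = [slice(None)] * x.ndim
    for ax in range(x.ndim - nspatial, x.ndim):
        sl[ax] = slice(0, (x.shape[ax] // 2) * 2)
    return x[tuple(sl)]


class MaxPool2d(Layer):
    """2x2 max pooling with floor behavior for odd sizes."""

    def forward(self, x, training=False):
        self._in_shape = x.shape
        xc = _pool_crop(x, 2)
        n, c, h, w = xc.shape
        r = xc.reshape(n, c, h // 2, 2, w // 2, 2)
        y = r.max(axis=(3, 5))
        mask = r == y[:, :, :, None, :, None]
        self._mask = mask / np.maximum(mask.sum(axis=(3, 5), keepdims=True), 1)
        return y.astype(DTYPE, copy=False)

    def backward(self, gy):
        g = self._mask * gy[:, :, :, None, :, None]
        n, c, h2, _, w2, _ = g.shape
        gx = np.zeros(self._in_shape, dtype=DTYPE)
        gx[:, :, : h2 * 2, : w2 * 2] = g.reshape(n, c, h2 * 2, w2 * 2)
        self._mask = None
        return gx


class MaxPool3d(Layer):
    """2x2x2 max pooling with floor behavior for odd sizes."""

    def forward(self, x, training=False):
        self._in_shape = x.shape
        xc = _pool_crop(x, 3)
        n, c, d, h, w = xc.shape
        r = xc.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        y = r.max(axis=(3, 5, 7))
        mask = r == y[:, :, :, None, :, None, :, None]
        self._mask = mask / np.maximum(mask.sum(axis=(3, 5, 7), keepdims=True), 1)
        return y.astype(DTYPE, copy=False)

    def backward(self, gy):
        g = self._mask * gy[:, :, :, None, :, None, :, None]
        n, c, d2, _, h2, _, w2, _ = g.shape
        gx = np.zeros(self._in_shape, dtype=DTYPE)
        gx[:, :, : d2 * 2, : h2 * 2, : w2 * 2] = g.reshape(n, c, d2 * 2, h2 * 2, w2 * 2)
        self._mask = None
        return gx


class GlobalAvgPool3d(Layer):
    """Average each 3D feature map to a single value: (N,C,D,H,W) -> (N,C)."""

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4)).astype(DTYPE, copy=False)

    def backward(self, gy):
        n, c, d, h, w = self._shape
        gx = np.broadcast_to(gy[:, :, None, None, None] / (d * h * w), self._shape)
        return gx.astype(DTYPE)


class Dense(Layer):
    def __init__(self, cin: int, cout: int, *, rng: np.random.Generator,
                 bias: bool = True) -> None:
        super().__init__()
        self.params["W"] = _he_init(rng, (cout, cin), cin)
        self.use_bias = bias
        if bias:
            self.params["b"] = np.zeros(cout, dtype=DTYPE)
        for key, v in self.params.items():
            self.grads[key] = np.zeros_like(v)

    def forward(self, x, training=False):
        self._x = x
        y = x @ self.params["W"].T
        if self.use_bias:
            y += self.params["b"]
        return y.astype(DTYPE, copy=False)

    def backward(self, gy):
        self.grads["W"] += gy.T @ self._x
        if self.use_bias:
            self.grads["b"] += gy.sum(axis=0)
        gx = gy @ self.params["W"]
        self._x = None
        return gx.astype(DTYPE, copy=False)
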