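"""Minimal NumPy neural-network stack for the lesion classifier.

Implements exactly the layer vocabulary the classifier needs — 2-D
convolution (TensorFlow-style ``same`` padding), valid max-pooling, batch
normalization, dropout, dense layers with ReLU/sigmoid activations — plus
the Adam optimizer and binary cross-entropy, all channels-last and
float32.  Every stochastic choice (weight init, shuffling, dropout masks)
is drawn from an explicit :class:`numpy.random.Generator`, so a fixed seed
gives bitwise-reproducible training in a single-threaded process.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2D",
    "MaxPool2D",
    "BatchNorm",
    "Dropout",
    "Flatten",
    "Dense",
    "Sequential",
    "TwoStreamNetwork",
    "Adam",
    "binary_cross_entropy",
]

_F32 = np.float32


def _act_forward(z: np.ndarray, activation: str) -> np.ndarray:
    if activation == "relu":
        return np.maximum(z, 0.0)
    if activation == "sigmoid":
        return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))
    if activation == "linear":
        return z
    raise ValueError(f"unknown activation {activation!r}")


def _act_backward(dout: np.ndarray, z: np.ndarray, a: np.ndarray, activation: str) -> np.ndarray:
    if activation == "relu":
        return dout * (z > 0)
    if activation == "sigmoid":
        return dout * a * (1.0 - a)
    if activation == "linear":
        return dout
    raise ValueError(f"unknown activation {activation!r}")


def same_pad_amount(n: int, kernel: int, stride: int) -> tuple[int, int]:
    """TensorFlow ``same`` padding for one spatial axis: output ceil(n/stride)."""
    out = -(-n // stride)
    total = max((out - 1) * stride + kernel - n, 0)
    before = total // 2
    return before, total - before


class Layer:
    """Base class; layers expose ``params``/``grads`` dicts after build."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def build(self, input_shape: tuple[int, ...], rng: np.random.Generator) -> tuple[int, ...]:
        return input_shape

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator | None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """Same-padded 2-D convolution via im2col, fused activation."""

    def __init__(self, filters: int, kernel_size: int, stride: int = 1,
                 activation: str = "relu") -> None:
        super().__init__()
        self.filters = int(filters)
        self.kernel = int(kernel_size)
        self.stride = int(stride)
        self.activation = activation

    def build(self, input_shape, rng):
        h, w, c = input_shape
        k = self.kernel
        fan_in = k * k * c
        # He initialization suits the ReLU stack
        self.params["W"] = (rng.standard_normal((fan_in, self.filters))
                            * np.sqrt(2.0 / fan_in)).astype(_F32)
        self.params["b"] = np.zeros(self.filters, dtype=_F32)
        self._in_shape = (h, w, c)
        self._pad_h = same_pad_amount(h, k, self.stride)
        self._pad_w = same_pad_amount(w, k, self.stride)
        oh = -(-h // self.stride)
        ow = -(-w // self.stride)
        self._out_hw = (oh, ow)
        return (oh, ow, self.filters)

    def _im2col(self, xp: np.ndarray) -> np.ndarray:
        k, s = self.kernel, self.stride
        # (N, OH, OW, C, k, k) view -> (N*OH*OW, k*k*C) copy
        win = sliding_window_view(xp, (k, k), axis=(1, 2))[:, ::s, ::s]
        n, oh, ow = win.shape[:3]
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * oh * ow, k * k * xp.shape[3])
        return np.ascontiguousarray(cols)

    def forward(self, x, training, rng=None):
        (pt, pb), (pl, pr) = self._pad_h, self._pad_w
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        cols = self._im2col(xp)
        z = cols @ self.params["W"] + self.params["b"]
        oh, ow = self._out_hw
        z = z.reshape(x.shape[0], oh, ow, self.filters)
        a = _act_forward(z, self.activation)
        if training:
            self._cache = (cols, z, a, x.shape, xp.shape)
        return a

    def backward(self, dout):
        cols, z, a, x_shape, xp_shape = self._cache
        dz = _act_backward(dout, z, a, self.activation)
        n, oh, ow, f = dz.shape
        dz2 = dz.reshape(n * oh * ow, f)
        self.grads["W"] = cols.T @ dz2
        self.grads["b"] = dz2.sum(axis=0)
        dcols = dz2 @ self.params["W"].T
        k, s = self.kernel, self.stride
        c = xp_shape[3]
        dcols = dcols.reshape(n, oh, ow, k, k, c)
        dxp = np.zeros(xp_shape, dtype=_F32)
        # scatter-add one kernel offset at a time (cheap strided adds)
        for di in range(k):
            for dj in range(k):
                dxp[:, di:di + oh * s:s, dj:dj + ow * s:s, :] += dcols[:, :, :, di, dj, :]
        (pt, _), (pl, _) = self._pad_h, self._pad_w
        h, w = x_shape[1], x_shape[2]
        return dxp[:, pt:pt + h, pl:pl + w, :]


class MaxPool2D(Layer):
    """Valid (unpadded) max pooling."""

    def __init__(self, pool_size: int = 3, stride: int = 2) -> None:
        super().__init__()
        self.pool = int(pool_size)
        self.stride = int(stride)

    def build(self, input_shape, rng):
        h, w, c = input_shape
        if h < self.pool or w < self.pool:
            raise ValueError(
                f"pool window {self.pool} exceeds input {h}x{w}; input image too small"
            )
        oh = (h - self.pool) // self.stride + 1
        ow = (w - self.pool) // self.stride + 1
        self._in_shape = (h, w, c)
        self._out_hw = (oh, ow)
        return (oh, ow, c)

    def forward(self, x, training, rng=None):
        p, s = self.pool, self.stride
        win = sliding_window_view(x, (p, p), axis=(1, 2))[:, ::s, ::s]
        n, oh, ow, c = win.shape[:4]
        win = win.reshape(n, oh, ow, c, p * p)
        idx = win.argmax(axis=-1)
        out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
        if training:
            self._cache = (idx, x.shape)
        return out

    def backward(self, dout):
        idx, x_shape = self._cache
        p, s = self.pool, self.stride
        oh, ow = self._out_hw
        dx = np.zeros(x_shape, dtype=_F32)
        for k in range(p * p):
            mask = idx == k
            if not mask.any():
                continue
            di, dj = divmod(k, p)
            dx[:, di:di + oh * s:s, dj:dj + ow * s:s, :] += dout * mask
        return dx


class BatchNorm(Layer):
    """Batch normalization over the channel axis (momentum 0.99, eps 1e-3)."""

    def __init__(self, momentum: float = 0.99, eps: float = 1e-3) -> None:
        super().__init__()
        self.momentum = momentum
        self.eps = eps

    def build(self, input_shape, rng):
        c = input_shape[-1]
        self.params["gamma"] = np.ones(c, dtype=_F32)
        self.params["beta"] = np.zeros(c, dtype=_F32)
        self.running_mean = np.zeros(c, dtype=_F32)
        self.running_var = np.ones(c, dtype=_F32)
        self._axes = tuple(range(len(input_shape)))  # (0,1,2) for NHWC after batch axis
        return input_shape

    def forward(self, x, training, rng=None):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(_F32)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(_F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        out = self.params["gamma"] * xhat + self.params["beta"]
        if training:
            self._cache = (xhat, inv_std, axes, x.shape)
        return out

    def backward(self, dout):
        xhat, inv_std, axes, x_shape = self._cache
        m = np.prod([x_shape[a] for a in axes])
        self.grads["gamma"] = (dout * xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        dxhat = dout * self.params["gamma"]
        dx = (inv_std / m) * (m * dxhat - dxhat.sum(axis=axes)
                              - xhat * (dxhat * xhat).sum(axis=axes))
        return dx.astype(_F32)


class Dropout(Layer):
    def __init__(self, rate: float = 0.5) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, training, rng=None):
        if not training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (rng.random(x.shape) < keep).astype(_F32) / keep
        self._mask = mask
        return x * mask

    def backward(self, dout):
        return dout * self._mask


class Flatten(Layer):
    def build(self, input_shape, rng):
        self._in_shape = input_shape
        return (int(np.prod(input_shape)),)

    def forward(self, x, training, rng=None):
        self._n = x.shape[0]
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape((self._n,) + self._in_shape)


class Dense(Layer):
    def __init__(self, units: int, activation: str = "linear") -> None:
        super().__init__()
        self.units = int(units)
        self.activation = activation

    def build(self, input_shape, rng):
        (fan_in,) = input_shape
        if self.activation == "relu":
            std = np.sqrt(2.0 / fan_in)
        else:  # Glorot for sigmoid / linear heads
            std = np.sqrt(1.0 / fan_in)
        self.params["W"] = (rng.standard_normal((fan_in, self.units)) * std).astype(_F32)
        self.params["b"] = np.zeros(self.units, dtype=_F32)
        return (self.units,)

    def forward(self, x, training, rng=None):
        z = x @ self.params["W"] + self.params["b"]
        a = _act_forward(z, self.activation)
        if training:
            self._cache = (x, z, a)
        return a

    def backward(self, dout, skip_activation: bool = False):
        x, z, a = self._cache
        dz = dout if skip_activation else _act_backward(dout, z, a, self.activation)
        self.grads["W"] = x.T @ dz
        self.grads["b"] = dz.sum(axis=0)
        return dz @ self.params["W"].T


def binary_cross_entropy(y_true: np.ndarray, p: np.ndarray, eps: float = 1e-7) -> float:
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y_true * np.log(p) + (1.0 - y_true) * np.log1p(-p)))


class Sequential:
    """Ordered layer stack with a sigmoid/linear head and manual backprop.

    ``backward_from_logits`` starts backpropagation at the pre-activation of
    the final Dense layer, so binary cross-entropy + sigmoid share the usual
    numerically stable fused gradient ``(p - y) / n``.
    """

    def __init__(self, layers: list[Layer], input_shape: tuple[int, ...], seed: int) -> None:
        self.layers = layers
        self.input_shape = tuple(input_shape)
        rng = np.random.default_rng(seed)
        shape = self.input_shape
        for layer in layers:
            shape = layer.build(shape, rng)
        self.output_shape = shape

    # -- inference ---------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        out = np.asarray(x, dtype=_F32)
        for layer in self.layers:
            out = layer.forward(out, training, rng)
        return out

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        outs = [self.forward(x[i:i + batch_size]) for i in range(0, len(x), batch_size)]
        return np.concatenate(outs, axis=0) if outs else np.empty((0,) + self.output_shape, _F32)

    # -- training ----------------------------------------------------------
    def backward_from_logits(self, dlogits: np.ndarray) -> None:
        last = self.layers[-1]
        if not isinstance(last, Dense):
            raise TypeError("backward_from_logits requires a Dense head")
        grad = last.backward(dlogits, skip_activation=True)
        for layer in reversed(self.layers[:-1]):
            grad = layer.backward(grad)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        grad = dout
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        for layer in self.layers:
            for name in layer.params:
                yield layer, name

    def get_weights(self) -> list[np.ndarray]:
        ws = [layer.params[name].copy() for layer, name in self.parameters()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                ws.append(layer.running_mean.copy())
                ws.append(layer.running_var.copy())
        return ws

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for layer, name in self.parameters():
            layer.params[name] = next(it).copy()
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                layer.running_mean = next(it).copy()
                layer.running_var = next(it).copy()


class TwoStreamNetwork:
    """Two trunks whose fused features feed one Dense head.

    Used for feature-level (parallel) fusion: each trunk is an identical
    headless classifier emitting a feature vector; the head is a single
    sigmoid unit over the fused features.  The default combiner
    concatenates the two vectors; ``combiner="average"`` averages them
    instead (halving the head's input width).
    """

    def __init__(self, trunk_a: Sequential, trunk_b: Sequential, head: Dense,
                 seed: int, combiner: str = "concat") -> None:
        if trunk_a.output_shape != trunk_b.output_shape:
            raise ValueError("trunks must emit features of identical shape")
        if combiner not in ("concat", "average"):
            raise ValueError("combiner must be 'concat' or 'average'")
        self.trunk_a = trunk_a
        self.trunk_b = trunk_b
        self.head = head
        self.combiner = combiner
        feat = trunk_a.output_shape[0]
        self.fused_features = 2 * feat if combiner == "concat" else feat
        rng = np.random.default_rng(seed)
        self.output_shape = head.build((self.fused_features,), rng)
        self._feat = feat

    def forward(self, x, training: bool = False, rng: np.random.Generator | None = None):
        xa, xb = x
        fa = self.trunk_a.forward(xa, training, rng)
        fb = self.trunk_b.forward(xb, training, rng)
        if self.combiner == "concat":
            fused = np.concatenate([fa, fb], axis=1)
        else:
            fused = 0.5 * (fa + fb)
        return self.head.forward(fused, training, rng)

    def predict(self, x, batch_size: int = 64) -> np.ndarray:
        xa, xb = x
        outs = [self.forward((xa[i:i + batch_size], xb[i:i + batch_size]))
                for i in range(0, len(xa), batch_size)]
        return np.concatenate(outs, axis=0) if outs else np.empty((0,) + self.output_shape, _F32)

    def backward_from_logits(self, dlogits: np.ndarray) -> None:
        dfused = self.head.backward(dlogits, skip_activation=True)
        if self.combiner == "concat":
            self.trunk_a.backward(dfused[:, :self._feat])
            self.trunk_b.backward(dfused[:, self._feat:])
        else:
            self.trunk_a.backward(0.5 * dfused)
            self.trunk_b.backward(0.5 * dfused)

    def parameters(self):
        yield from self.trunk_a.parameters()
        yield from self.trunk_b.parameters()
        for name in self.head.params:
            yield self.head, name

    def get_weights(self) -> list[np.ndarray]:
        return (self.trunk_a.get_weights() + self.trunk_b.get_weights()
                + [self.head.params[n].copy() for n in self.head.params])

    def set_weights(self, weights: list[np.ndarray]) -> None:
        na = len(self.trunk_a.get_weights())
        self.trunk_a.set_weights(weights[:na])
        self.trunk_b.set_weights(weights[na:2 * na])
        for name, w in zip(self.head.params, weights[2 * na:]):
            self.head.params[name] = w.copy()


class Adam:
    """Adam optimizer (beta1 0.9, beta2 0.999, eps 1e-7)."""

    def __init__(self, network, learning_rate: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7) -> None:
        self.network = network
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m: dict[tuple[int, str], np.ndarray] = {}
        self._v: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for layer, name in self.network.parameters():
            g = layer.grads[name]
            key = (id(layer), name)
            m = self._m.get(key)
            if m is None:
                m = np.zeros_like(g)
                self._v[key] = np.zeros_like(g)
            v = self._v[key]
            m = b1 * m + (1 - b1) * g
            v = b2 * v + (1 - b2) * g * g
            self._m[key], self._v[key] = m, v
            layer.params[name] -= (self.lr * (m / bias1)
                                   / (np.sqrt(v / bias2) + self.eps)).astype(_F32)
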