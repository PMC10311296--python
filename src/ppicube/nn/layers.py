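"""Minimal neural-network engine on numpy arrays.

Implements exactly the layers the cube models need — 3D convolution,
batch normalization, ReLU, block average pooling, dense layers, inverted
dropout — with hand-written backward passes, plus softmax cross-entropy
and mean-squared-error losses and an Adam optimizer.  Data layout is
channels-last: ``(N, D, H, W, C)`` for volumetric tensors.

Convolutions use 'same'-style symmetric padding of (k-1)//2 and are
computed as one matmul per kernel offset, which keeps peak memory small
and runs on BLAS.  All layers are deterministic given their seeds.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv3d",
    "BatchNorm",
    "ReLU",
    "AvgPool3d",
    "Flatten",
    "Dense",
    "Dropout",
    "Sequential",
    "softmax",
    "softmax_cross_entropy",
    "mse_loss",
    "Adam",
]


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv3d(Layer):
    """3D convolution, channels-last, symmetric padding (k-1)//2."""

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.k, self.s = kernel, stride
        self.c_in, self.c_out = c_in, c_out
        fan_in = kernel ** 3 * c_in
        self.w = Param(_he_init(rng, (kernel, kernel, kernel, c_in, c_out),
                                fan_in, dtype), "conv_w")
        self.b = Param(np.zeros(c_out, dtype=dtype), "conv_b")

    def params(self):
        return [self.w, self.b]

    def _out_size(self, d: int) -> int:
        p = (self.k - 1) // 2
        return (d + 2 * p - self.k) // self.s + 1

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        k, s = self.k, self.s
        p = (k - 1) // 2
        n, d, h, w_, c = x.shape
        od, oh, ow = self._out_size(d), self._out_size(h), self._out_size(w_)
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))
        self._xp_shape = xp.shape
        self._x_slices = []
        out = np.zeros((n * od * oh * ow, self.c_out), dtype=x.dtype)
        for kd in range(k):
            for kh in range(k):
                for kw in range(k):
                    sl = xp[:, kd:kd + s * od:s, kh:kh + s * oh:s,
                            kw:kw + s * ow:s, :]
                    flat = sl.reshape(-1, c)
                    if train:
                        self._x_slices.append(flat)
                    out += flat @ self.w.value[kd, kh, kw].reshape(c, self.c_out)
        out += self.b.value
        self._out_dims = (n, od, oh, ow)
        return out.reshape(n, od, oh, ow, self.c_out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        k, s = self.k, self.s
        p = (k - 1) // 2
        n, od, oh, ow = self._out_dims
        g = grad.reshape(-1, self.c_out)
        self.b.grad += g.sum(axis=0)
        gxp = np.zeros(self._xp_shape, dtype=grad.dtype)
        idx = 0
        for kd in range(k):
            for kh in range(k):
                for kw in range(k):
                    flat = self._x_slices[idx]
                    idx += 1
                    self.w.grad[kd, kh, kw] += (flat.T @ g).reshape(
                        self.c_in, self.c_out)
                    gslice = g @ self.w.value[kd, kh, kw].reshape(
                        self.c_in, self.c_out).T
                    gxp[:, kd:kd + s * od:s, kh:kh + s * oh:s,
                        kw:kw + s * ow:s, :] += gslice.reshape(n, od, oh, ow,
                                                               self.c_in)
        self._x_slices = []
        if p:
            return gxp[:, p:-p, p:-p, p:-p, :]
        return gxp


class BatchNorm(Layer):
    """Batch normalization over all axes but the last (channel) axis."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = Param(np.ones(c, dtype=dtype), "bn_gamma")
        self.beta = Param(np.zeros(c, dtype=dtype), "bn_beta")
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        flat = x.reshape(-1, x.shape[-1])
        if train:
            mean = flat.mean(axis=0)
            var = flat.var(axis=0)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(self.running_mean.dtype)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(self.running_var.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (flat - mean) * inv
        if train:
            self._xhat, self._inv = xhat, inv
        out = xhat * self.gamma.value + self.beta.value
        return out.reshape(self._shape).astype(x.dtype)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = grad.reshape(-1, grad.shape[-1])
        m = g.shape[0]
        self.gamma.grad += (g * self._xhat).sum(axis=0)
        self.beta.grad += g.sum(axis=0)
        gx = (self.gamma.value * self._inv / m) * (
            m * g - g.sum(axis=0) - self._xhat * (g * self._xhat).sum(axis=0))
        return gx.reshape(self._shape).astype(grad.dtype)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class AvgPool3d(Layer):
    """Block average pooling down to a fixed spatial size.

    The input spatial extent must be a multiple of the target size.
    """

    def __init__(self, out_size: int):
        self.out_size = out_size

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, d, h, w, c = x.shape
        t = self.out_size
        if d % t or h % t or w % t:
            raise ValueError(f"spatial size {d} not divisible by pool target {t}")
        f = d // t
        self._f, self._in_shape = f, x.shape
        return x.reshape(n, t, f, t, f, t, f, c).mean(axis=(2, 4, 6))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, d, h, w, c = self._in_shape
        f, t = self._f, self.out_size
        g = grad / f ** 3
        g = np.broadcast_to(
            g[:, :, None, :, None, :, None, :], (n, t, f, t, f, t, f, c))
        return g.reshape(self._in_shape).astype(grad.dtype)


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int,
                 rng: np.random.Generator | None = None, dtype=np.float32,
                 zero_init: bool = False):
        rng = rng or np.random.default_rng(0)
        if zero_init:
            w = np.zeros((n_in, n_out), dtype=dtype)
        else:
            w = _he_init(rng, (n_in, n_out), n_in, dtype)
        self.w = Param(w, "dense_w")
        self.b = Param(np.zeros(n_out, dtype=dtype), "dense_b")

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value.T


class Dropout(Layer):
    """Inverted dropout; identity in eval mode; seeded for reproducibility."""

    def __init__(self, rate: float, seed: int = 0):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.seed = seed
        self.rng = np.random.default_rng(seed)

    def reset(self, seed: int | None = None) -> None:
        self.rng = np.random.default_rng(self.seed if seed is None else seed)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray,
    labels: np.ndarray,
    class_weights: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Weighted categorical cross-entropy with integrated softmax.

    ``labels`` are integer class indices.  Returns (mean loss, gradient
    w.r.t. logits).  Per-sample losses are scaled by the weight of the
    true class.
    """
    n = logits.shape[0]
    probs = softmax(logits.astype(np.float64))
    w = (np.ones(n) if class_weights is None
         else np.asarray(class_weights, dtype=float)[labels])
    logp = np.log(np.clip(probs[np.arange(n), labels], 1e-300, None))
    loss = float(-(w * logp).mean())
    grad = probs
    grad[np.arange(n), labels] -= 1.0
    grad *= (w / n)[:, None]
    return loss, grad.astype(logits.dtype)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient w.r.t. ``pred``."""
    pred = pred.reshape(-1)
    target = np.asarray(target, dtype=float).reshape(-1)
    if pred.shape != target.shape:
        raise ValueError("prediction/target length mismatch")
    diff = pred.astype(np.float64) - target
    loss = float((diff ** 2).mean())
    grad = (2.0 / diff.size) * diff
    return loss, grad.astype(np.float32).reshape(-1, 1)


class Adam:
    """Adam optimizer over a list of :class:`Param`."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.value -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                p.value.dtype)
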