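"""Minimal numpy neural-network core.

Implements exactly the building blocks the pipeline's models need —
dimension-preserving 2-D convolution, max-pooling, dense layers, ReLU /
sigmoid / softmax activations, inverted dropout, the Adam optimizer and
softmax cross-entropy / mean-squared-error losses — with explicit backprop.
Tensors are channels-last ``(batch, height, width, channels)`` float32.

The convolution uses "same" (zero) padding so that a kernel of size
``2k+1`` preserves spatial dimensions, the padding rule required both by
the autoencoder (``dim(I) = dim(decode(encode(I)))``) and by the printed
pooling arithmetic of the slide classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

# ---------------------------------------------------------------------------
# activations


def sigmoid(x):
    """Logistic function 1 / (1 + e^-x), elementwise, in (0, 1)."""
    x = np.asarray(x, dtype=np.float64)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


def relu(x):
    """max(0, x) elementwise."""
    out = np.maximum(0, np.asarray(x))
    return out if out.ndim else float(out)


def apply_activation(x, kind: str):
    """Apply a named activation (``"sigmoid"`` or ``"relu"``)."""
    if kind == "sigmoid":
        return sigmoid(x)
    if kind == "relu":
        return relu(x)
    raise ValueError(f"unknown activation kind {kind!r}")


def softmax(z, axis: int = -1):
    """Normalized exponential over ``axis``; shift-invariant and sums to 1."""
    z = np.asarray(z, dtype=np.float64)
    if z.size == 0:
        raise ValueError("softmax of an empty vector is undefined")
    if not np.all(np.isfinite(z)):
        raise ValueError("softmax requires finite logits")
    shifted = z - z.max(axis=axis, keepdims=True)
    ez = np.exp(shifted)
    return ez / ez.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# Adam (first/second gradient-moment optimizer)


@dataclass(frozen=True)
class AdamSpec:
    """Adam hyperparameters; defaults follow the training setup used
    throughout the pipeline (lr 0.001, beta1 0.9, beta2 0.999)."""

    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self):
        if not (0 <= self.beta1 < 1 and 0 <= self.beta2 < 1):
            raise ValueError("moment decay rates must lie in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class AdamState:
    """Per-parameter moment accumulators, zero-initialized at t = 0."""

    m: np.ndarray
    v: np.ndarray
    t: int = 0

    @classmethod
    def zeros_like(cls, theta) -> "AdamState":
        theta = np.asarray(theta, dtype=np.float64)
        return cls(m=np.zeros_like(theta), v=np.zeros_like(theta), t=0)


def adam_step(theta, g, state: AdamState, spec: AdamSpec = AdamSpec()):
    """One Adam update.

    m_t = b1 m_{t-1} + (1-b1) g ;  v_t = b2 v_{t-1} + (1-b2) g^2 ;
    theta' = theta - lr * m_hat / (sqrt(v_hat) + eps), with the usual
    bias corrections m_hat = m_t/(1-b1^t), v_hat = v_t/(1-b2^t).
    """
    theta = np.asarray(theta, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if theta.shape != g.shape:
        raise ValueError("parameter and gradient shapes disagree")
    t = state.t + 1
    m = spec.beta1 * state.m + (1 - spec.beta1) * g
    v = spec.beta2 * state.v + (1 - spec.beta2) * g**2
    m_hat = m / (1 - spec.beta1**t)
    v_hat = v / (1 - spec.beta2**t)
    theta_new = theta - spec.learning_rate * m_hat / (np.sqrt(v_hat) + spec.eps)
    return theta_new, AdamState(m=m, v=v, t=t)


class Adam:
    """Stateful Adam over a list of named parameter arrays (in-place)."""

    def __init__(self, spec: AdamSpec = AdamSpec()):
        self.spec = spec
        self._states: dict[int, AdamState] = {}

    def step(self, params: list[tuple[np.ndarray, np.ndarray]]) -> None:
        for key, (theta, grad) in enumerate(params):
            state = self._states.get(key)
            if state is None:
                state = AdamState.zeros_like(theta)
            new_theta, new_state = adam_step(theta, grad, state, self.spec)
            theta[...] = new_theta.astype(theta.dtype)
            self._states[key] = new_state


# ---------------------------------------------------------------------------
# layers


class Layer:
    def forward(self, x, *, train: bool = False, rng=None):
        raise NotImplementedError

    def backward(self, dout):
        raise NotImplementedError

    def out_shape(self, in_shape: tuple) -> tuple:
        return in_shape

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return []

    def init(self, in_shape: tuple, rng) -> tuple:
        return self.out_shape(in_shape)


class Conv2D(Layer):
    """Same-padded 2-D convolution with an odd square kernel."""

    def __init__(self, filters: int, kernel_size: int = 3):
        if kernel_size % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.filters = filters
        self.k = kernel_size
        self.W = None  # (k*k*in_ch, filters)
        self.b = None

    def init(self, in_shape, rng):
        h, w, c = in_shape
        fan_in = self.k * self.k * c
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.W = (rng.standard_normal((fan_in, self.filters)) * scale).astype(
            np.float32
        )
        self.b = np.zeros(self.filters, dtype=np.float32)
        self.in_channels = c
        return (h, w, self.filters)

    def out_shape(self, in_shape):
        h, w, _ = in_shape
        return (h, w, self.filters)

    def _im2col(self, x):
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        # (B, H, W, k, k, C) -> (B*H*W, k*k*C)
        win = sliding_window_view(xp, (self.k, self.k), axis=(1, 2))
        win = win.transpose(0, 1, 2, 4, 5, 3)
        return np.ascontiguousarray(win).reshape(-1, self.k * self.k * x.shape[3])

    def forward(self, x, *, train=False, rng=None):
        b, h, w, _ = x.shape
        cols = self._im2col(x.astype(np.float32))
        out = cols @ self.W + self.b
        self._cache = (cols, x.shape)
        return out.reshape(b, h, w, self.filters)

    def backward(self, dout):
        cols, x_shape = self._cache
        b, h, w, c = x_shape
        dflat = dout.reshape(-1, self.filters).astype(np.float32)
        self.dW = cols.T @ dflat
        self.db = dflat.sum(axis=0)
        dcols = (dflat @ self.W.T).reshape(b, h, w, self.k, self.k, c)
        p = self.k // 2
        dxp = np.zeros((b, h + 2 * p, w + 2 * p, c), dtype=np.float32)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, i : i + h, j : j + w, :] += dcols[:, :, :, i, j, :]
        return dxp[:, p : p + h, p : p + w, :]

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class MaxPool2D(Layer):
    """Non-overlapping max pooling; stride equals the window size."""

    def __init__(self, pool: int):
        self.p = pool

    def out_shape(self, in_shape):
        h, w, c = in_shape
        if h % self.p or w % self.p:
            raise ValueError(
                f"spatial size {h}x{w} not divisible by pooling window {self.p}"
            )
        return (h // self.p, w // self.p, c)

    def init(self, in_shape, rng):
        return self.out_shape(in_shape)

    def forward(self, x, *, train=False, rng=None):
        b, h, w, c = x.shape
        self.out_shape((h, w, c))
        xr = x.reshape(b, h // self.p, self.p, w // self.p, self.p, c)
        out = xr.max(axis=(2, 4))
        self._cache = (xr, out)
        return out

    def backward(self, dout):
        xr, out = self._cache
        mask = xr == out[:, :, None, :, None, :]
        dxr = mask * dout[:, :, None, :, None, :]
        b, hp, p, wp, _, c = xr.shape
        return dxr.reshape(b, hp * p, wp * p, c)


class Upsample2D(Layer):
    """Nearest-neighbour upsampling by an integer factor (decoder side)."""

    def __init__(self, factor: int):
        self.f = factor

    def out_shape(self, in_shape):
        h, w, c = in_shape
        return (h * self.f, w * self.f, c)

    def init(self, in_shape, rng):
        return self.out_shape(in_shape)

    def forward(self, x, *, train=False, rng=None):
        return x.repeat(self.f, axis=1).repeat(self.f, axis=2)

    def backward(self, dout):
        b, h, w, c = dout.shape
        return dout.reshape(b, h // self.f, self.f, w // self.f, self.f, c).sum(
            axis=(2, 4)
        )


class Flatten(Layer):
    def out_shape(self, in_shape):
        return (int(np.prod(in_shape)),)

    def init(self, in_shape, rng):
        return self.out_shape(in_shape)

    def forward(self, x, *, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape: tuple):
        self.shape = shape

    def out_shape(self, in_shape):
        return self.shape

    def init(self, in_shape, rng):
        return self.shape

    def forward(self, x, *, train=False, rng=None):
        self._in = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, dout):
        return dout.reshape(self._in)


class Dense(Layer):
    def __init__(self, units: int):
        self.units = units
        self.W = None
        self.b = None

    def init(self, in_shape, rng):
        (n,) = in_shape
        scale = np.sqrt(2.0 / n)
        self.W = (rng.standard_normal((n, self.units)) * scale).astype(np.float32)
        self.b = np.zeros(self.units, dtype=np.float32)
        return (self.units,)

    def out_shape(self, in_shape):
        return (self.units,)

    def forward(self, x, *, train=False, rng=None):
        self._x = x.astype(np.float32)
        return self._x @ self.W + self.b

    def backward(self, dout):
        dout = dout.astype(np.float32)
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class ReLU(Layer):
    def forward(self, x, *, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Sigmoid(Layer):
    def forward(self, x, *, train=False, rng=None):
        self._out = sigmoid(x).astype(np.float32)
        return self._out

    def backward(self, dout):
        return dout * self._out * (1 - self._out)


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def forward(self, x, *, train=False, rng=None):
        if not train or self.rate == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * self._mask.astype(np.float32)

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Sequential:
    """A feed-forward stack with cached activations for backprop/Grad-CAM."""

    def __init__(self, layers: list[Layer], input_shape: tuple, seed: int = 0):
        self.layers = layers
        self.input_shape = tuple(input_shape)
        rng = np.random.default_rng(seed)
        shape = self.input_shape
        self._shapes = [shape]
        for layer in layers:
            shape = layer.init(shape, rng)
            self._shapes.append(shape)
        self.output_shape = shape

    def output_shapes(self) -> list[tuple]:
        """Per-layer output shapes (index 0 is the input shape)."""
        return list(self._shapes)

    def forward(self, x, *, train: bool = False, rng=None, keep_outputs: bool = False):
        x = np.asarray(x, dtype=np.float32)
        if x.shape[1:] != self.input_shape:
            raise ValueError(
                f"input shape {x.shape[1:]} != expected {self.input_shape}"
            )
        self._outputs = [x] if keep_outputs else None
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
            if keep_outputs:
                self._outputs.append(x)
        return x

    def backward(self, dout, upto: int = 0):
        """Backpropagate ``dout``; returns the gradient w.r.t. the output of
        layer ``upto - 1`` (i.e. the input of layer ``upto``)."""
        for layer in reversed(self.layers[upto:]):
            dout = layer.backward(dout)
        return dout

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def n_parameters(self) -> int:
        return sum(int(theta.size) for theta, _ in self.params())

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Learned parameters keyed for serialization."""
        out = {}
        for i, layer in enumerate(self.layers):
            for j, (theta, _) in enumerate(_param_arrays(layer)):
                out[f"layer{i}_p{j}"] = theta
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for j, theta in enumerate([p for p, _ in _param_arrays(layer)]):
                theta[...] = arrays[f"layer{i}_p{j}"]


def _param_arrays(layer: Layer):
    if isinstance(layer, Conv2D):
        return [(layer.W, None), (layer.b, None)]
    if isinstance(layer, Dense):
        return [(layer.W, None), (layer.b, None)]
    return []


# ---------------------------------------------------------------------------
# losses


def softmax_cross_entropy(logits, y):
    """Mean sparse categorical cross-entropy and its logit gradient."""
    y = np.asarray(y)
    n, k = logits.shape
    if y.min() < 0 or y.max() >= k:
        raise ValueError(f"label outside [0, {k}) in training batch")
    probs = softmax(logits, axis=1)
    loss = float(-np.log(np.clip(probs[np.arange(n), y], 1e-12, None)).mean())
    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, (dlogits / n).astype(np.float32)


def mse_loss(pred, target):
    """Mean squared error and its gradient w.r.t. ``pred``."""
    diff = pred.astype(np.float32) - target.astype(np.float32)
    loss = float(np.mean(diff**2))
    return loss, (2.0 / diff.size) * diff
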