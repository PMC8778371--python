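"""A compact numpy CNN engine.

Implements exactly the layer vocabulary the orientation-classification
networks need — unpadded stride-1 convolution, 2x2 max pooling, global
max pooling, inverted dropout, dense layers, a softmax output trained
with categorical cross-entropy, and the Adam optimizer. Data layout is
channels-last float32: (batch, height, width, channels).

Convolutions are evaluated as one GEMM per batch over an im2col patch
matrix, which keeps the arithmetic inside BLAS.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_SELU_ALPHA = 1.6732632423543772
_SELU_LAMBDA = 1.0507009873554805


class _Act:
    """Hidden-layer activation with in-place float32 forward/backward.

    ``apply(z)`` may overwrite the pre-activation buffer and returns
    ``(y, cache)``; ``grad(dz, y, cache)`` multiplies dz by f'(z) in place.
    The cache holds whatever backward needs beyond y (for most activations
    f'(z) is recoverable from y alone, which avoids keeping z around).
    """

    name = "?"

    def apply(self, z):
        raise NotImplementedError

    def grad(self, dz, y, cache):
        raise NotImplementedError


class _ReLU(_Act):
    name = "ReLU"

    def apply(self, z):
        np.maximum(z, 0.0, out=z)
        return z, None

    def grad(self, dz, y, cache):
        dz[y <= 0] = 0.0
        return dz


class _ELU(_Act):
    name = "ELU"

    def apply(self, z):
        neg = np.minimum(z, 0.0)
        np.expm1(neg, out=neg)
        np.maximum(z, 0.0, out=z)
        z += neg
        return z, None

    def grad(self, dz, y, cache):
        # f' = 1 for z > 0, f + 1 for z <= 0, i.e. min(y + 1, 1)
        dz *= np.minimum(y + 1.0, 1.0)
        return dz


class _SELU(_Act):
    name = "SELU"

    def apply(self, z):
        neg = np.minimum(z, 0.0)
        np.expm1(neg, out=neg)
        neg *= _SELU_ALPHA
        np.maximum(z, 0.0, out=z)
        z += neg
        z *= _SELU_LAMBDA
        return z, None

    def grad(self, dz, y, cache):
        # f' = lambda for z > 0, y + lambda*alpha for z <= 0
        dz *= np.where(y > 0, np.float32(_SELU_LAMBDA),
                       y + np.float32(_SELU_LAMBDA * _SELU_ALPHA))
        return dz


class _Sigmoid(_Act):
    name = "Si"

    def apply(self, z):
        np.negative(z, out=z)
        np.exp(z, out=z)
        z += 1.0
        np.reciprocal(z, out=z)
        return z, None

    def grad(self, dz, y, cache):
        dz *= y
        dz *= 1.0 - y
        return dz


class _SoftPlus(_Act):
    name = "SP"

    def apply(self, z):
        sig = 1.0 / (1.0 + np.exp(-z))  # sigmoid(z) = f'(z), cached
        y = np.logaddexp(0.0, z, out=z)
        return y, sig

    def grad(self, dz, y, cache):
        dz *= cache
        return dz


class _SoftSign(_Act):
    name = "SS"

    def apply(self, z):
        denom = 1.0 + np.abs(z)
        z /= denom
        return z, denom

    def grad(self, dz, y, cache):
        dz /= cache
        dz /= cache
        return dz


class _TanH(_Act):
    name = "TanH"

    def apply(self, z):
        np.tanh(z, out=z)
        return z, None

    def grad(self, dz, y, cache):
        dz *= 1.0 - y * y
        return dz


_ACTIVATIONS: dict[str, type[_Act]] = {
    a.name: a for a in (_ReLU, _ELU, _SELU, _Sigmoid, _SoftPlus, _SoftSign, _TanH)
}


def _activation(name: str) -> _Act:
    if name not in _ACTIVATIONS:
        raise ValueError(f"unknown activation {name!r}")
    return _ACTIVATIONS[name]()


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def init_params(self, rng: np.random.Generator) -> None:
        pass

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))


class Conv2D(Layer):
    """Valid (unpadded) stride-1 convolution with a fused activation."""

    def __init__(self, kernel_size: int, filters: int, activation: str,
                 is_input_layer: bool = False) -> None:
        super().__init__()
        self.k = int(kernel_size)
        self.filters = int(filters)
        self.activation_name = activation
        self.act = _activation(activation)
        self.is_input_layer = is_input_layer  # skip input-gradient work
        self.in_channels: int | None = None

    def build(self, in_channels: int, rng: np.random.Generator) -> None:
        self.in_channels = in_channels
        fan_in = self.k * self.k * in_channels
        fan_out = self.k * self.k * self.filters
        limit = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
        w = rng.uniform(-limit, limit, (fan_in, self.filters)).astype(np.float32)
        b = np.zeros(self.filters, dtype=np.float32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x, training, rng):
        B, H, W, C = x.shape
        if H < self.k or W < self.k:
            raise ValueError(
                f"input {H}x{W} smaller than the {self.k}x{self.k} convolution kernel"
            )
        if self.in_channels is None:
            raise RuntimeError("layer used before initialization")
        oh, ow = H - self.k + 1, W - self.k + 1
        patches = sliding_window_view(x, (self.k, self.k), axis=(1, 2))
        # (B, oh, ow, C, k, k) -> (B*oh*ow, k*k*C) matching weight layout
        cols = np.ascontiguousarray(patches.transpose(0, 1, 2, 4, 5, 3)).reshape(
            B * oh * ow, self.k * self.k * self.in_channels)
        z = cols @ self.params[0]
        z += self.params[1]
        y, act_cache = self.act.apply(z)
        if training:
            self._cache = (cols, y, act_cache, (B, H, W, C, oh, ow))
        return y.reshape(B, oh, ow, self.filters)

    def backward(self, dout):
        cols, y, act_cache, (B, H, W, C, oh, ow) = self._cache
        dz = self.act.grad(
            np.ascontiguousarray(dout.reshape(-1, self.filters)), y, act_cache)
        self.grads[0][...] = cols.T @ dz
        self.grads[1][...] = dz.sum(axis=0)
        self._cache = None
        if self.is_input_layer:
            return None
        dcols = dz @ self.params[0].T
        dcols = dcols.reshape(B, oh, ow, self.k, self.k, C)
        dx = np.zeros((B, H, W, C), dtype=np.float32)
        for i in range(self.k):
            for j in range(self.k):
                dx[:, i:i + oh, j:j + ow, :] += dcols[:, :, :, i, j, :]
        return dx


class MaxPool2D(Layer):
    """2x2 (or p x p) max pooling, stride = pool size, floor semantics."""

    def __init__(self, pool_size: int = 2) -> None:
        super().__init__()
        self.p = int(pool_size)

    def forward(self, x, training, rng):
        B, H, W, C = x.shape
        p = self.p
        oh, ow = H // p, W // p
        if oh < 1 or ow < 1:
            raise ValueError(f"input {H}x{W} too small for {p}x{p} max pooling")
        r = x[:, :oh * p, :ow * p, :].reshape(B, oh, p, ow, p, C)
        if not training:
            return r.max(axis=(2, 4))
        windows = r.transpose(0, 1, 3, 5, 2, 4).reshape(B, oh, ow, C, p * p)
        idx = windows.argmax(axis=-1)
        out = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, (B, H, W, C, oh, ow))
        return out

    def backward(self, dout):
        idx, (B, H, W, C, oh, ow) = self._cache
        p = self.p
        dwin = np.zeros((B, oh, ow, C, p * p), dtype=np.float32)
        np.put_along_axis(dwin, idx[..., None], dout[..., None], axis=-1)
        dx = np.zeros((B, H, W, C), dtype=np.float32)
        dx[:, :oh * p, :ow * p, :] = (
            dwin.reshape(B, oh, ow, C, p, p).transpose(0, 1, 4, 2, 5, 3)
            .reshape(B, oh * p, ow * p, C))
        self._cache = None
        return dx


class GlobalMaxPool(Layer):
    """Reduce each feature map to its maximum: (B, H, W, C) -> (B, C)."""

    def forward(self, x, training, rng):
        B, H, W, C = x.shape
        flat = x.reshape(B, H * W, C)
        if not training:
            return flat.max(axis=1)
        idx = flat.argmax(axis=1)
        out = np.take_along_axis(flat, idx[:, None, :], axis=1)[:, 0, :]
        self._cache = (idx, (B, H, W, C))
        return out

    def backward(self, dout):
        idx, (B, H, W, C) = self._cache
        dflat = np.zeros((B, H * W, C), dtype=np.float32)
        np.put_along_axis(dflat, idx[:, None, :], dout[:, None, :], axis=1)
        self._cache = None
        return dflat.reshape(B, H, W, C)


class Dropout(Layer):
    """Inverted dropout: active only while training, identity at inference."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 < rate < 1.0:
            raise ValueError(f"dropout rate must lie in (0, 1), got {rate}")
        self.rate = float(rate)

    def forward(self, x, training, rng):
        if not training:
            return x
        keep = 1.0 - self.rate
        mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        self._cache = mask
        return x * mask

    def backward(self, dout):
        mask = self._cache
        self._cache = None
        return dout * mask


class Dense(Layer):
    """Fully connected layer; activation 'SM' marks the softmax output."""

    def __init__(self, units: int, activation: str) -> None:
        super().__init__()
        self.units = int(units)
        self.activation_name = activation
        self.act = None if activation == "SM" else _activation(activation)
        self.in_features: int | None = None

    def build(self, in_features: int, rng: np.random.Generator) -> None:
        self.in_features = in_features
        limit = np.sqrt(6.0 / (in_features + self.units))
        w = rng.uniform(-limit, limit, (in_features, self.units)).astype(np.float32)
        b = np.zeros(self.units, dtype=np.float32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x, training, rng):
        z = x @ self.params[0]
        z += self.params[1]
        if self.activation_name == "SM":
            y, act_cache = softmax(z), None
        else:
            y, act_cache = self.act.apply(z)
        if training:
            self._cache = (x, y, act_cache)
        return y

    def backward(self, dout):
        # for the SM output layer, `dout` must already be dL/dz = (p - t)/N
        x, y, act_cache = self._cache
        dz = dout if self.activation_name == "SM" else \
            self.act.grad(np.ascontiguousarray(dout), y, act_cache)
        self.grads[0][...] = x.T @ dz
        self.grads[1][...] = dz.sum(axis=0)
        self._cache = None
        return dz @ self.params[0].T


def softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return (e / e.sum(axis=-1, keepdims=True)).astype(np.float32)


class Model:
    """A plain sequential network over the layers above."""

    def __init__(self, layers: list[Layer], input_channels: int = 1, seed: int = 0) -> None:
        self.layers = layers
        self.input_channels = input_channels
        self.seed = seed
        self.reinitialize(seed)

    def reinitialize(self, seed: int) -> None:
        """(Re)draw all weights with Glorot-uniform initialization."""
        self.seed = seed
        rng = np.random.default_rng(seed)
        channels = self.input_channels
        for layer in self.layers:
            if isinstance(layer, Conv2D):
                layer.build(channels, rng)
                channels = layer.filters
            elif isinstance(layer, Dense):
                layer.build(channels, rng)
                channels = layer.units

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        if training and rng is None:
            raise ValueError("training-mode forward pass needs an rng for dropout")
        out = x
        for layer in self.layers:
            out = layer.forward(out, training, rng)
        return out

    def backward(self, dout: np.ndarray) -> None:
        grad = dout
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Inference-mode class probabilities for a stack of images (N, H, W[, C])."""
        if x.ndim == 3:
            x = x[..., None]
        outs = [self.forward(x[i:i + batch_size]) for i in range(0, len(x), batch_size)]
        return np.concatenate(outs, axis=0)

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        own = self.params
        if len(own) != len(weights):
            raise ValueError("weight list does not match the model")
        for p, w in zip(own, weights):
            p[...] = w

    def save_weights(self, path) -> None:
        np.savez(path, *self.params)

    def load_weights(self, path) -> None:
        with np.load(path) as data:
            self.set_weights([data[k] for k in data.files])


class Adam:
    """Adam optimizer with the usual bias correction."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7) -> None:
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)
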