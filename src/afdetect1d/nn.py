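"""Compact NumPy engine for 1D convolutional networks.

Implements exactly the layer set the ECG classifier needs — valid 1D
convolution, ReLU, batch normalization, max/average pooling (size 2,
stride 2), dropout, flatten, dense — plus softmax cross-entropy and the
Adam optimizer.  Activations are stored as ``(batch, length, channels)``
float32 arrays; convolutions are evaluated as an im2col reshape followed
by a single BLAS matmul, which is what keeps desk-scale training of the
~3.2M-parameter network practical on one CPU.

Every layer exposes ``forward(x, train)`` and ``backward(grad)``;
trainable parameters live in ``layer.params`` (name → ndarray) with
gradients accumulated in ``layer.grads`` under the same keys.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1D",
    "ReLU",
    "BatchNorm",
    "MaxPool",
    "AvgPool",
    "Dropout",
    "Flatten",
    "Dense",
    "Network",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]

_DTYPE = np.float32


class Layer:
    """Base layer: no parameters, identity shapes."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    # non-trainable state (e.g. BN running statistics)
    def state_arrays(self) -> dict[str, np.ndarray]:
        return {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1D(Layer):
    """Valid (no padding) 1D convolution, stride 1.

    Weight shape ``(kernel, in_channels, filters)``; He-uniform init.
    """

    def __init__(self, kernel: int, in_channels: int, filters: int, rng: np.random.Generator):
        super().__init__()
        if kernel < 1 or in_channels < 1 or filters < 1:
            raise ValueError("kernel, in_channels and filters must be positive")
        self.kernel = kernel
        self.in_channels = in_channels
        self.filters = filters
        fan_in = kernel * in_channels
        limit = np.sqrt(6.0 / fan_in)
        self.params["W"] = rng.uniform(-limit, limit, size=(kernel, in_channels, filters)).astype(_DTYPE)
        self.params["b"] = np.zeros(filters, dtype=_DTYPE)

    def _w2(self) -> np.ndarray:
        # (kernel, c, f) -> (k*c, f); row index j*c + ch matches the im2col layout
        return self.params["W"].reshape(self.kernel * self.in_channels, self.filters)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, length, c = x.shape
        k = self.kernel
        if length < k:
            raise ValueError(f"input length {length} shorter than kernel {k}")
        out_len = length - k + 1
        # im2col via k contiguous block copies (fast path; a strided
        # sliding-window reshape hits numpy's slow generic copy)
        col = np.empty((b, out_len, k, c), dtype=_DTYPE)
        for j in range(k):
            col[:, :, j, :] = x[:, j : j + out_len, :]
        col2 = col.reshape(b * out_len, k * c)
        out = col2 @ self._w2() + self.params["b"]
        self._cache = (col2, x.shape)
        return out.reshape(b, out_len, self.filters)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        col2, x_shape = self._cache
        b, length, c = x_shape
        k = self.kernel
        out_len = length - k + 1
        g2 = grad.reshape(b * out_len, self.filters)
        self.grads["W"] = (col2.T @ g2).reshape(k, c, self.filters)
        self.grads["b"] = g2.sum(axis=0)
        dcol = (g2 @ self._w2().T).reshape(b, out_len, k, c)
        dx = np.zeros(x_shape, dtype=_DTYPE)
        for j in range(k):  # k is 3/5/7: cheap scatter-add
            dx[:, j : j + out_len, :] += dcol[:, :, j, :]
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0)
        self._out = out
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * (self._out > 0)


class BatchNorm(Layer):
    """Per-channel batch normalization over (batch, length).

    Trainable scale ``gamma`` and shift ``beta``; non-trainable running
    mean/variance updated with momentum during training and used at
    inference.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(channels, dtype=_DTYPE)
        self.params["beta"] = np.zeros(channels, dtype=_DTYPE)
        self.running_mean = np.zeros(channels, dtype=_DTYPE)
        self.running_var = np.ones(channels, dtype=_DTYPE)

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        x2 = x.reshape(-1, x.shape[-1])
        if train:
            mean = x2.mean(axis=0)
            var = np.einsum("nc,nc->c", x2, x2) / x2.shape[0] - mean * mean
            np.maximum(var, 0, out=var)
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(_DTYPE)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(_DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(_DTYPE)
        # fused affine y = a*x + c with a = gamma/std, c = beta - mean*a
        a = self.params["gamma"] * inv_std
        self._cache = (x, mean.astype(_DTYPE), inv_std, train)
        return x * a + (self.params["beta"] - mean.astype(_DTYPE) * a)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, mean, inv_std, trained = self._cache
        xhat = (x - mean) * inv_std
        self.grads["gamma"] = (grad * xhat).sum(axis=tuple(range(grad.ndim - 1)))
        self.grads["beta"] = grad.sum(axis=tuple(range(grad.ndim - 1)))
        g = grad * self.params["gamma"]
        if not trained:
            return (g * inv_std).astype(_DTYPE)
        axes = tuple(range(grad.ndim - 1))
        # full batch-statistics gradient
        dx = (g - g.mean(axis=axes) - xhat * (g * xhat).mean(axis=axes)) * inv_std
        return dx.astype(_DTYPE)


class _Pool2(Layer):
    """Size-2, stride-2 pooling; an odd trailing sample is dropped (floor)."""

    def _pairs(self, x: np.ndarray) -> np.ndarray:
        b, length, c = x.shape
        self._in_shape = x.shape
        out_len = length // 2
        return x[:, : 2 * out_len, :].reshape(b, out_len, 2, c)


class MaxPool(_Pool2):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        pairs = self._pairs(x)
        self._argmax = pairs.argmax(axis=2)
        return pairs.max(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, length, c = self._in_shape
        out_len = length // 2
        dx = np.zeros(self._in_shape, dtype=_DTYPE)
        dpairs = dx[:, : 2 * out_len, :].reshape(b, out_len, 2, c)
        idx = self._argmax[:, :, None, :] == np.arange(2)[None, None, :, None]
        np.copyto(dpairs, np.where(idx, grad[:, :, None, :], 0))
        return dx


class AvgPool(_Pool2):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return self._pairs(x).mean(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, length, c = self._in_shape
        out_len = length // 2
        dx = np.zeros(self._in_shape, dtype=_DTYPE)
        dx[:, : 2 * out_len, :].reshape(b, out_len, 2, c)[:] = 0.5 * grad[:, :, None, :]
        return dx


class Dropout(Layer):
    """Inverted dropout: active only during training, identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(_DTYPE) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._in_shape)


class Dense(Layer):
    def __init__(self, in_units: int, out_units: int, rng: np.random.Generator):
        super().__init__()
        limit = np.sqrt(6.0 / in_units)
        self.params["W"] = rng.uniform(-limit, limit, size=(in_units, out_units)).astype(_DTYPE)
        self.params["b"] = np.zeros(out_units, dtype=_DTYPE)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ grad
        self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["W"].T


def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max-shift for numerical stability."""
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean cross-entropy of softmax(logits) against one-hot targets.

    Returns ``(loss, probabilities, dlogits)`` where ``dlogits`` is the
    gradient of the mean loss with respect to the logits.
    """
    probs = softmax(logits)
    n = logits.shape[0]
    loss = float(-(onehot * np.log(np.clip(probs, 1e-12, None))).sum() / n)
    dlogits = ((probs - onehot) / n).astype(_DTYPE)
    return loss, probs, dlogits


class Network:
    """An ordered stack of layers ending in 4-class logits."""

    def __init__(self, layers: list[Layer], input_len: int):
        self.layers = layers
        self.input_len = input_len

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim == 2:
            x = x[:, :, None]
        if x.shape[1] != self.input_len:
            raise ValueError(f"expected input length {self.input_len}, got {x.shape[1]}")
        out = np.ascontiguousarray(x, dtype=_DTYPE)
        for layer in self.layers:
            out = layer.forward(out, train)
        return out

    def backward(self, dlogits: np.ndarray) -> None:
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def trainable_parameters(self) -> list[tuple[str, np.ndarray]]:
        out = []
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params.items():
                out.append((f"{i}.{type(layer).__name__}.{name}", arr))
        return out

    def n_trainable(self) -> int:
        """Parameter count reported from the actual weight arrays."""
        return int(sum(arr.size for _, arr in self.trainable_parameters()))

    def gradients(self) -> list[np.ndarray]:
        return [layer.grads[name] for layer in self.layers for name in layer.params]


class Adam:
    """Adam optimizer: bias-corrected first/second moment estimates.

    Update: ``theta <- theta - lr * m_hat / (sqrt(v_hat) + eps)``.
    """

    def __init__(self, net: Network, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.net = net
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._params = [arr for _, arr in net.trainable_parameters()]
        self.m = [np.zeros_like(p) for p in self._params]
        self.v = [np.zeros_like(p) for p in self._params]

    def step(self) -> None:
        self.t += 1
        grads = self.net.gradients()
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self._params, grads, self.m, self.v):
            g = g.astype(p.dtype)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
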