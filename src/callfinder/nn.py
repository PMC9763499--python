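"""Minimal CNN engine: layers with explicit backprop, in float32 numpy.

Provides exactly the pieces a residual spectrogram classifier needs —
2-D convolution (im2col + BLAS matmul), batch normalization, ReLU, basic
residual blocks, global average pooling, a linear head, softmax
cross-entropy, and Adam.  Layers cache what their backward pass needs, so
the usage pattern is the classic ``loss = f(net.forward(x)); net.backward(dy)``
followed by an optimizer step over ``net.parameters()``.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np

DTYPE = np.float32


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Layer:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def parameters(self) -> List[Param]:
        return []

    def state_arrays(self) -> List[Tuple[str, np.ndarray]]:
        """All persistent arrays (weights and running statistics), in order."""
        return [(p.name, p.value) for p in self.parameters()]

    def load_state(self, arrays: List[np.ndarray]) -> None:
        for p in self.parameters():
            p.value[...] = arrays.pop(0)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """Unfold (N,C,H,W) into (N*Ho*Wo, C*k*k) patches."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, k, k)
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(dcols: np.ndarray, x_shape, k: int, stride: int, pad: int) -> np.ndarray:
    """Scatter-add column gradients back onto the (padded) input."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    dx_p = np.zeros((n, c, hp, wp), dtype=dcols.dtype)
    dcols = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for ki in range(k):
        for kj in range(k):
            dx_p[:, :, ki : ki + stride * ho : stride, kj : kj + stride * wo : stride] += dcols[
                :, :, :, :, ki, kj
            ]
    if pad:
        return dx_p[:, :, pad : hp - pad, pad : wp - pad]
    return dx_p


class Conv2d(Layer):
    """2-D convolution without bias (batch norm follows every conv here)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        rng: Optional[np.random.Generator] = None,
        name: str = "conv",
    ) -> None:
        rng = rng or np.random.default_rng()
        fan_out = out_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_out)  # Kaiming normal, fan-out mode
        weight = rng.normal(0.0, std, size=(out_channels, in_channels, kernel_size, kernel_size))
        self.weight = Param(weight, name=f"{name}.weight")
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        cols, ho, wo = _im2col(x, self.kernel_size, self.stride, self.padding)
        w_mat = self.weight.value.reshape(self.weight.value.shape[0], -1)
        out = cols @ w_mat.T  # (N*Ho*Wo, out_c)
        n = x.shape[0]
        out = out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)
        if train:
            self._cache = (cols, x.shape)
        return np.ascontiguousarray(out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache
        n, oc, ho, wo = dy.shape
        dy_mat = dy.transpose(0, 2, 3, 1).reshape(-1, oc)
        w_mat = self.weight.value.reshape(oc, -1)
        self.weight.grad += (dy_mat.T @ cols).reshape(self.weight.value.shape)
        dcols = dy_mat @ w_mat
        return _col2im(dcols, x_shape, self.kernel_size, self.stride, self.padding)

    def parameters(self) -> List[Param]:
        return [self.weight]


class BatchNorm2d(Layer):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5, name: str = "bn") -> None:
        self.gamma = Param(np.ones(channels), name=f"{name}.gamma")
        self.beta = Param(np.zeros(channels), name=f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self.name = name
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        x_hat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        out = self.gamma.value[None, :, None, None] * x_hat + self.beta.value[None, :, None, None]
        if train:
            self._cache = (x_hat, inv_std)
        return out.astype(DTYPE, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x_hat, inv_std = self._cache
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dgamma = (dy * x_hat).sum(axis=(0, 2, 3))
        dbeta = dy.sum(axis=(0, 2, 3))
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        g = self.gamma.value[None, :, None, None]
        dx_hat = dy * g
        dx = (
            dx_hat
            - dx_hat.mean(axis=(0, 2, 3), keepdims=True)
            - x_hat * (dx_hat * x_hat).mean(axis=(0, 2, 3), keepdims=True)
        ) * inv_std[None, :, None, None]
        return dx.astype(DTYPE, copy=False)

    def parameters(self) -> List[Param]:
        return [self.gamma, self.beta]

    def state_arrays(self) -> List[Tuple[str, np.ndarray]]:
        return super().state_arrays() + [
            (f"{self.name}.running_mean", self.running_mean),
            (f"{self.name}.running_var", self.running_var),
        ]

    def load_state(self, arrays: List[np.ndarray]) -> None:
        super().load_state(arrays)
        self.running_mean = arrays.pop(0).astype(DTYPE)
        self.running_var = arrays.pop(0).astype(DTYPE)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self) -> List[Param]:
        return [p for layer in self.layers for p in layer.parameters()]

    def state_arrays(self):
        return [item for layer in self.layers for item in layer.state_arrays()]

    def load_state(self, arrays: List[np.ndarray]) -> None:
        for layer in self.layers:
            layer.load_state(arrays)


class BasicBlock(Layer):
    """Two 3x3 convolutions with a residual shortcut.

    The shortcut is the identity when shape is preserved, otherwise a strided
    1x1 projection convolution followed by batch norm.
    """

    def __init__(self, in_channels: int, out_channels: int, stride: int, rng, name: str) -> None:
        self.conv1 = Conv2d(in_channels, out_channels, 3, stride, 1, rng, f"{name}.conv1")
        self.bn1 = BatchNorm2d(out_channels, name=f"{name}.bn1")
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_channels, out_channels, 3, 1, 1, rng, f"{name}.conv2")
        self.bn2 = BatchNorm2d(out_channels, name=f"{name}.bn2")
        self.relu2 = ReLU()
        if stride != 1 or in_channels != out_channels:
            self.proj: Optional[Sequential] = Sequential(
                Conv2d(in_channels, out_channels, 1, stride, 0, rng, f"{name}.proj"),
                BatchNorm2d(out_channels, name=f"{name}.proj_bn"),
            )
        else:
            self.proj = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        out = self.bn2.forward(self.conv2.forward(out, train), train)
        shortcut = self.proj.forward(x, train) if self.proj is not None else x
        return self.relu2.forward(out + shortcut, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dsum = self.relu2.backward(dy)
        dmain = self.bn2.backward(dsum)
        dmain = self.conv2.backward(dmain)
        dmain = self.relu1.backward(dmain)
        dmain = self.bn1.backward(dmain)
        dmain = self.conv1.backward(dmain)
        dshort = self.proj.backward(dsum) if self.proj is not None else dsum
        return dmain + dshort

    def parameters(self) -> List[Param]:
        params = (
            self.conv1.parameters()
            + self.bn1.parameters()
            + self.conv2.parameters()
            + self.bn2.parameters()
        )
        if self.proj is not None:
            params += self.proj.parameters()
        return params

    def state_arrays(self):
        items = (
            self.conv1.state_arrays()
            + self.bn1.state_arrays()
            + self.conv2.state_arrays()
            + self.bn2.state_arrays()
        )
        if self.proj is not None:
            items += self.proj.state_arrays()
        return items

    def load_state(self, arrays: List[np.ndarray]) -> None:
        for layer in (self.conv1, self.bn1, self.conv2, self.bn2):
            layer.load_state(arrays)
        if self.proj is not None:
            self.proj.load_state(arrays)


class GlobalAvgPool(Layer):
    """Adaptive global average pooling: (N,C,H,W) -> (N,C) for any H, W."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng=None, name: str = "fc") -> None:
        rng = rng or np.random.default_rng()
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Param(rng.uniform(-bound, bound, size=(out_features, in_features)), f"{name}.weight")
        self.bias = Param(np.zeros(out_features), f"{name}.bias")

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.weight.grad += dy.T @ self._x
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.value

    def parameters(self) -> List[Param]:
        return [self.weight, self.bias]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, targets: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    probs = softmax(logits.astype(np.float64))
    loss = -np.log(np.maximum(probs[np.arange(n), targets], 1e-12)).mean()
    grad = probs
    grad[np.arange(n), targets] -= 1.0
    return float(loss), (grad / n).astype(DTYPE)


class Adam:
    """Adam optimizer with bias correction; zero-grads after each step."""

    def __init__(
        self,
        params: Sequence[Param],
        lr: float = 1e-5,
        beta1: float = 0.5,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.grad[...] = 0.0
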