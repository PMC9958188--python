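"""Minimal NumPy layer library with explicit backpropagation.

Tensors flow as (C, L, H, W, D) arrays (single complex per pass, matching
the batch-size-1 training regime). Every layer implements ``forward`` /
``backward`` and exposes its parameters for the optimizer; backward passes
are exact gradients validated against finite differences in the tests.
"""

from __future__ import annotations

import numpy as np


class Parameter:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class SeqSpatialConv(Layer):
    """Convolution over (sequence, H, W, D) with a 4-axis kernel.

    Kernel spans ``seq_kernel`` positions along the sequence axis (stride
    ``seq_stride``, padding ``seq_pad``) and 3x3x3 spatially (stride 1,
    padding 1). ``seq_kernel=1`` degenerates to an independent per-unit 3D
    convolution (the 3D baseline's building block).
    """

    SPATIAL_K = 3

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        seq_kernel: int = 3,
        seq_stride: int = 1,
        seq_pad: int | None = None,
        rng: np.random.Generator | None = None,
        name: str = "conv",
    ):
        self.cin = in_channels
        self.cout = out_channels
        self.lk = seq_kernel
        self.ls = seq_stride
        self.lp = seq_pad if seq_pad is not None else (seq_kernel - 1) // 2
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * seq_kernel * self.SPATIAL_K**3
        scale = np.sqrt(2.0 / fan_in)  # He init for the ReLU nonlinearity
        self.weight = Parameter(
            rng.normal(0.0, scale, size=(out_channels, fan_in)), f"{name}.weight"
        )
        self.bias = Parameter(np.zeros(out_channels), f"{name}.bias")
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def out_seq_len(self, L: int) -> int:
        n = L + 2 * self.lp - self.lk
        if n < 0:
            raise ValueError(f"sequence length {L} shorter than kernel {self.lk}")
        return n // self.ls + 1

    def _columns(self, xp: np.ndarray, j: int) -> np.ndarray:
        """im2col for one output sequence position -> (H*W*D, cin*lk*27)."""
        k = self.SPATIAL_K
        window = xp[:, j * self.ls : j * self.ls + self.lk]  # (cin, lk, H+2, W+2, D+2)
        view = np.lib.stride_tricks.sliding_window_view(window, (k, k, k), axis=(2, 3, 4))
        # view: (cin, lk, H, W, D, k, k, k) -> (H, W, D, cin, lk, k, k, k)
        view = view.transpose(2, 3, 4, 0, 1, 5, 6, 7)
        h, w, d = view.shape[:3]
        return np.ascontiguousarray(view).reshape(h * w * d, -1)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        cin, L, H, W, D = x.shape
        if cin != self.cin:
            raise ValueError(f"expected {self.cin} channels, got {cin}")
        Lout = self.out_seq_len(L)
        p = (self.SPATIAL_K - 1) // 2
        xp = np.pad(
            x, ((0, 0), (self.lp, self.lp), (p, p), (p, p), (p, p)), mode="constant"
        )
        out = np.empty((self.cout, Lout, H, W, D))
        cols_cache = [] if training else None
        for j in range(Lout):
            cols = self._columns(xp, j)
            res = cols @ self.weight.value.T + self.bias.value  # (HWD, cout)
            out[:, j] = res.T.reshape(self.cout, H, W, D)
            if training:
                cols_cache.append(cols)
        if training:
            self._cache = (x.shape, cols_cache)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        (cin, L, H, W, D), cols_cache = self._cache
        k = self.SPATIAL_K
        p = (k - 1) // 2
        Lout = grad.shape[1]
        dxp = np.zeros((cin, L + 2 * self.lp, H + 2 * p, W + 2 * p, D + 2 * p))
        for j in range(Lout):
            g = grad[:, j].reshape(self.cout, -1).T  # (HWD, cout)
            self.weight.grad += g.T @ cols_cache[j]
            self.bias.grad += g.sum(axis=0)
            dcols = (g @ self.weight.value).reshape(H, W, D, cin, self.lk, k, k, k)
            base = j * self.ls
            for kl in range(self.lk):
                for kh in range(k):
                    for kw in range(k):
                        for kd in range(k):
                            dxp[
                                :, base + kl,
                                kh : kh + H, kw : kw + W, kd : kd + D,
                            ] += dcols[:, :, :, :, kl, kh, kw, kd].transpose(3, 0, 1, 2)
        self._cache = None
        return dxp[
            :, self.lp : self.lp + L, p : p + H, p : p + W, p : p + D
        ]


class BatchNormChannels(Layer):
    """Per-channel normalization over all non-channel axes (batch of one)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels), "bn.gamma")
        self.beta = Parameter(np.zeros(channels), "bn.beta")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def _shape(self, x):
        return (-1,) + (1,) * (x.ndim - 1)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = tuple(range(1, x.ndim))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        sh = self._shape(x)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(sh)) * inv_std.reshape(sh)
        if training:
            self._cache = (xhat, inv_std, axes)
        return self.gamma.value.reshape(sh) * xhat + self.beta.value.reshape(sh)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std, axes = self._cache
        sh = self._shape(grad)
        n = xhat.size // xhat.shape[0]
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = grad * self.gamma.value.reshape(sh)
        dxhat_sum = g.sum(axis=axes, keepdims=True)
        dxhat_x_sum = (g * xhat).sum(axis=axes, keepdims=True)
        dx = inv_std.reshape(sh) * (g - dxhat_sum / n - xhat * dxhat_x_sum / n)
        self._cache = None
        return dx


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = grad * self._mask
        self._mask = None
        return out


class SpatialMaxPool(Layer):
    """2x2x2 / stride-2 max pool over the spatial axes of (C, L, H, W, D).

    Identity when the spatial edge is already below the kernel size, so
    reduced-extent configurations remain well-defined.
    """

    def __init__(self, kernel: int = 2):
        self.kernel = kernel
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        k = self.kernel
        C, L, H, W, D = x.shape
        if H < k:
            if training:
                self._cache = ("identity", x.shape)
            return x
        if H % k or W % k or D % k:
            raise ValueError(f"spatial dims {(H, W, D)} not divisible by {k}")
        view = x.reshape(C, L, H // k, k, W // k, k, D // k, k)
        view = view.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
            C, L, H // k, W // k, D // k, k**3
        )
        arg = view.argmax(axis=-1)
        out = np.take_along_axis(view, arg[..., None], axis=-1)[..., 0]
        if training:
            self._cache = (arg, x.shape)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        tag, shape = self._cache[0], self._cache[1]
        self._cache = None
        if isinstance(tag, str):  # identity branch
            return grad
        arg = tag
        k = self.kernel
        C, L, H, W, D = shape
        dview = np.zeros((C, L, H // k, W // k, D // k, k**3))
        np.put_along_axis(dview, arg[..., None], grad[..., None], axis=-1)
        dview = dview.reshape(C, L, H // k, W // k, D // k, k, k, k)
        return dview.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(C, L, H, W, D)


class GlobalSpatialAvgPool(Layer):
    """Average over (H, W, D): (C, L, H, W, D) -> (C, L)."""

    def __init__(self):
        self._shape = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        C, L, H, W, D = self._shape
        self._shape = None
        return np.broadcast_to(
            grad[:, :, None, None, None], (C, L, H, W, D)
        ) / (H * W * D)


class Linear(Layer):
    """Dense map from a flat vector to ``out_features`` scalars."""

    def __init__(
        self,
        in_features: int,
        out_features: int = 1,
        rng: np.random.Generator | None = None,
        name: str = "head",
    ):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(1.0 / in_features)
        self.weight = Parameter(
            rng.normal(0.0, scale, size=(out_features, in_features)), f"{name}.weight"
        )
        self.bias = Parameter(np.zeros(out_features), f"{name}.bias")
        self._x = None

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = x.reshape(-1)
        if training:
            self._x = x
        return self.weight.value @ x + self.bias.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = np.atleast_1d(grad)
        self.weight.grad += np.outer(grad, self._x)
        self.bias.grad += grad
        dx = self.weight.value.T @ grad
        self._x = None
        return dx


def mse_loss(pred: np.ndarray, target: float) -> tuple[float, np.ndarray]:
    """Scalar mean-squared error and its gradient w.r.t. pred."""
    pred = np.atleast_1d(pred)
    diff = pred - target
    return float(np.mean(diff**2)), 2.0 * diff / diff.size
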