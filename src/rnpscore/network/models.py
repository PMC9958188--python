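"""Scoring network architectures.

``build_4dcnn`` realizes the sequence+spatial convolutional stack
(channels [64,128,256,512,512], sequence strides [2,2,2,1,1], kernel 3,
spatial 2x2x2 max-pooling after the first four blocks, global spatial
average after the fifth, linear head). ``build_3dcnn`` is the per-unit
baseline that doubles channels from 64 while halving the spatial extent
to 1 and mean-pools over real (mask=1) units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..errors import ScoringShapeError
from .layers import (
    BatchNormChannels,
    GlobalSpatialAvgPool,
    Layer,
    Linear,
    Parameter,
    ReLU,
    SeqSpatialConv,
    SpatialMaxPool,
)

DEFAULT_CONV_CHANNELS = (64, 128, 256, 512, 512)
DEFAULT_SEQ_STRIDES = (2, 2, 2, 1, 1)


@dataclass
class NetworkConfig:
    conv_channels: tuple[int, ...] = DEFAULT_CONV_CHANNELS
    seq_strides: tuple[int, ...] = DEFAULT_SEQ_STRIDES
    seq_kernel: int = 3
    pool_kernel: int = 2
    batch_norm: bool = True
    head: str = "regression"  # or "classification"
    in_channels: int = 3
    L: int = 128
    grid_size: int = 32

    def __post_init__(self):
        self.conv_channels = tuple(self.conv_channels)
        self.seq_strides = tuple(self.seq_strides)
        if len(self.conv_channels) != len(self.seq_strides):
            raise ValueError("conv_channels and seq_strides must have equal length")
        if self.L % self.stride_product:
            raise ValueError(
                f"L={self.L} not divisible by product of strides "
                f"{self.stride_product}"
            )
        if self.head not in ("regression", "classification"):
            raise ValueError(f"unknown head {self.head!r}")

    @property
    def stride_product(self) -> int:
        return math.prod(self.seq_strides)

    @property
    def final_seq_len(self) -> int:
        return self.L // self.stride_product

    @property
    def flattened_length(self) -> int:
        return self.conv_channels[-1] * self.final_seq_len

    @property
    def input_shape(self) -> tuple[int, int, int, int, int]:
        return (self.in_channels, self.L, self.grid_size, self.grid_size, self.grid_size)

    def to_dict(self) -> dict:
        return {
            "conv_channels": list(self.conv_channels),
            "seq_strides": list(self.seq_strides),
            "seq_kernel": self.seq_kernel,
            "pool_kernel": self.pool_kernel,
            "batch_norm": self.batch_norm,
            "head": self.head,
            "in_channels": self.in_channels,
            "L": self.L,
            "grid_size": self.grid_size,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


class ScoringModel:
    """A stack of layers ending in a scalar-output linear head.

    ``kind`` is "4d" (sequence-mixing convolutions, padding slices are
    zeros) or "3d" (per-unit convolutions + mask-aware mean over units).
    """

    def __init__(self, kind: str, config: NetworkConfig, layers: list[Layer],
                 head: Linear):
        self.kind = kind
        self.config = config
        self.layers = layers
        self.head = head
        self._mask_cache = None

    # -- parameters / state ------------------------------------------------

    def parameters(self) -> list[Parameter]:
        params = []
        for layer in self.layers:
            params.extend(layer.parameters())
        params.extend(self.head.parameters())
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self.layers + [self.head]):
            for j, p in enumerate(layer.parameters()):
                state[f"layer{i}.param{j}"] = p.value.copy()
            if isinstance(layer, BatchNormChannels):
                state[f"layer{i}.running_mean"] = layer.running_mean.copy()
                state[f"layer{i}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers + [self.head]):
            for j, p in enumerate(layer.parameters()):
                p.value = np.array(state[f"layer{i}.param{j}"], dtype=np.float64)
                p.grad = np.zeros_like(p.value)
            if isinstance(layer, BatchNormChannels):
                layer.running_mean = np.array(state[f"layer{i}.running_mean"])
                layer.running_var = np.array(state[f"layer{i}.running_var"])

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.parameters())

    # -- forward / backward ------------------------------------------------

    def check_input(self, x: np.ndarray) -> None:
        if tuple(x.shape) != self.config.input_shape:
            raise ScoringShapeError(
                f"expected input shape {self.config.input_shape}, got {tuple(x.shape)}"
            )

    def forward(
        self,
        x: np.ndarray,
        mask: np.ndarray | None = None,
        training: bool = False,
    ) -> float:
        self.check_input(x)
        out = np.asarray(x, dtype=np.float64)
        for layer in self.layers:
            out = layer.forward(out, training=training)
        if self.kind == "3d":
            # (C, L, 1, 1, 1) -> mask-aware mean over units -> (C,)
            out = out.reshape(out.shape[0], out.shape[1])
            if mask is None:
                mask = np.ones(out.shape[1])
            sel = np.flatnonzero(mask)
            if len(sel) == 0:
                raise ScoringShapeError("3D baseline requires at least one real unit")
            pooled = out[:, sel].mean(axis=1)
            if training:
                self._mask_cache = (out.shape, sel)
            out = pooled
        score = self.head.forward(out, training=training)
        return float(score[0])

    def backward(self, dscore: float) -> None:
        grad = self.head.backward(np.array([dscore]))
        if self.kind == "3d":
            shape, sel = self._mask_cache
            g = np.zeros(shape)
            g[:, sel] = grad[:, None] / len(sel)
            grad = g.reshape(shape[0], shape[1], 1, 1, 1)
            self._mask_cache = None
        else:
            # undo the head's implicit flatten of the (C, L) representation
            grad = grad.reshape(self.config.conv_channels[-1], -1)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = np.zeros_like(p.value)

    def score(self, tensor, training: bool = False) -> float:
        """Score a ComplexTensor (duck-typed: .data and .mask)."""
        return self.forward(tensor.data, mask=tensor.mask, training=training)


def build_4dcnn(config: NetworkConfig, seed: int = 0) -> ScoringModel:
    """Five sequence+spatial conv blocks, global spatial average, linear head."""
    rng = np.random.default_rng(seed)
    layers: list[Layer] = []
    cin = config.in_channels
    n_blocks = len(config.conv_channels)
    for b, (cout, stride) in enumerate(zip(config.conv_channels, config.seq_strides)):
        layers.append(
            SeqSpatialConv(
                cin, cout,
                seq_kernel=config.seq_kernel,
                seq_stride=stride,
                rng=rng,
                name=f"block{b + 1}.conv",
            )
        )
        if config.batch_norm:
            layers.append(BatchNormChannels(cout))
        layers.append(ReLU())
        if b < n_blocks - 1:
            layers.append(SpatialMaxPool(config.pool_kernel))
        else:
            layers.append(GlobalSpatialAvgPool())
        cin = cout
    head = Linear(config.flattened_length, 1, rng=rng)
    return ScoringModel("4d", config, layers, head)


def build_3dcnn(
    config: NetworkConfig, seed: int = 0, base_channels: int = 64
) -> ScoringModel:
    """Per-unit 3D conv baseline: channels double while spatial halves to 1."""
    if config.grid_size & (config.grid_size - 1):
        raise ValueError("3D baseline requires a power-of-two spatial extent")
    rng = np.random.default_rng(seed)
    n_blocks = int(math.log2(config.grid_size))
    layers: list[Layer] = []
    cin = config.in_channels
    cout = base_channels
    for b in range(n_blocks):
        layers.append(
            SeqSpatialConv(
                cin, cout, seq_kernel=1, seq_stride=1, rng=rng,
                name=f"block{b + 1}.conv",
            )
        )
        if config.batch_norm:
            layers.append(BatchNormChannels(cout))
        layers.append(ReLU())
        layers.append(SpatialMaxPool(config.pool_kernel))
        cin = cout
        if b < n_blocks - 1:
            cout *= 2
    head = Linear(cin, 1, rng=rng)
    return ScoringModel("3d", config, layers, head)
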