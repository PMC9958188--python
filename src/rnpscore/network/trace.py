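"""Symbolic shape tracer for the sequence+spatial conv stack.

Computes, without instantiating weights, the (channels, sequence length,
spatial extent) progression through every conv / pool stage, mirroring
the runtime arithmetic of :mod:`rnpscore.network.models` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

from ..errors import TraceError
from .models import NetworkConfig


@dataclass
class LayerShape:
    layer_index: int  # 1-based block number; 0 = input
    stage: str  # "input" | "conv" | "pool" | "global_pool"
    channels: int
    seq_length: int
    spatial: tuple[int, int, int]

    def __post_init__(self):
        if self.channels < 1 or self.seq_length < 1 or min(self.spatial) < 1:
            raise TraceError(f"degenerate shape at block {self.layer_index}: {self}")


def trace_shapes(
    config: NetworkConfig,
    input_shape: tuple[int, ...] | None = None,
) -> list[LayerShape]:
    """Per-stage shape progression for the 4D stack.

    ``input_shape`` may be (C, L, H, W, D) or (1, C, L, H, W, D); defaults
    to the config's input shape.
    """
    shape = tuple(input_shape) if input_shape is not None else config.input_shape
    if len(shape) == 6:
        if shape[0] != 1:
            raise TraceError("leading batch dimension must be 1")
        shape = shape[1:]
    if len(shape) != 5:
        raise TraceError(f"expected a 5D input shape, got {shape}")
    c, L, h, w, d = shape

    pad = (config.seq_kernel - 1) // 2
    trace = [LayerShape(0, "input", c, L, (h, w, d))]
    n_blocks = len(config.conv_channels)
    for b, (cout, stride) in enumerate(
        zip(config.conv_channels, config.seq_strides), start=1
    ):
        span = L + 2 * pad - config.seq_kernel
        if span < 0:
            raise TraceError(f"sequence length {L} too short at block {b}")
        if stride > 1 and L % stride:
            raise TraceError(
                f"sequence length {L} not divisible by stride {stride} at block {b}"
            )
        L = span // stride + 1
        trace.append(LayerShape(b, "conv", cout, L, (h, w, d)))
        if b < n_blocks:
            k = config.pool_kernel
            if h >= k:
                if h % k or w % k or d % k:
                    raise TraceError(
                        f"spatial dims {(h, w, d)} not divisible by pool kernel {k}"
                    )
                h, w, d = h // k, w // k, d // k
            trace.append(LayerShape(b, "pool", cout, L, (h, w, d)))
        else:
            h = w = d = 1
            trace.append(LayerShape(b, "global_pool", cout, L, (h, w, d)))
        c = cout
    return trace


def flattened_length(trace: list[LayerShape]) -> int:
    """Length of the final representation vector (channels x sequence)."""
    last = trace[-1]
    if last.spatial != (1, 1, 1):
        raise TraceError("trace does not end in a globally pooled representation")
    return last.channels * last.seq_length


def conv_seq_lengths(trace: list[LayerShape]) -> list[int]:
    """Sequence length after each block's convolution."""
    return [s.seq_length for s in trace if s.stage == "conv"]
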