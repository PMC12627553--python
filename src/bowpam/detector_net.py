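"""The spectrogram-tile CNN: declarative architecture, closed-form parameter
count, construction, and scoring.

The default architecture is a stack of 7 valid (unpadded) square
convolutions with kernel sizes [7, 5, 5, 3, 3, 3, 3], stride 1, channels
growing 1 -> 5 -> 10 -> 20 -> 40 -> 60 -> 80 -> 100, each followed by ReLU,
2x2 max-pooling and dropout (rate 0.2); global average pooling collapses the
remaining spatial extent to a 100-vector which feeds dense layers of 128 and
32 units and a single logistic output unit.  The closed-form trainable
parameter count of this stack is 167,899.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ._nn import (Adam, Conv2D, Dense, Dropout, GlobalAvgPool, MaxPool2,
                  ReLU, sigmoid)

DEFAULT_KERNELS = (7, 5, 5, 3, 3, 3, 3)
DEFAULT_CHANNELS = (1, 5, 10, 20, 40, 60, 80, 100)
DEFAULT_CLASSIFIER = (128, 32)


@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative description of the detector network."""

    kernel_sizes: Tuple[int, ...] = DEFAULT_KERNELS
    channels: Tuple[int, ...] = DEFAULT_CHANNELS
    classifier_widths: Tuple[int, ...] = DEFAULT_CLASSIFIER
    stride: int = 1
    pool_size: int = 2
    dropout_rate: float = 0.2
    output_units: int = 1

    def __post_init__(self):
        object.__setattr__(self, "kernel_sizes", tuple(self.kernel_sizes))
        object.__setattr__(self, "channels", tuple(self.channels))
        object.__setattr__(self, "classifier_widths", tuple(self.classifier_widths))
        if len(self.kernel_sizes) != len(self.channels) - 1:
            raise ValueError("need len(kernel_sizes) == len(channels) - 1")
        if any(k % 2 == 0 or k < 1 for k in self.kernel_sizes):
            raise ValueError("kernels must be odd and positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.stride != 1 or self.pool_size != 2:
            raise ValueError("only stride 1 / pool size 2 are supported")
        if self.output_units != 1:
            raise ValueError("binary head: output_units must be 1")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ArchitectureSpec":
        return cls(**json.loads(text))


def count_parameters(spec: ArchitectureSpec) -> int:
    """Closed-form trainable parameter count of the built network.

    Sum over conv layers of c_in*c_out*k^2 + c_out, plus the dense stack
    channels[-1] -> classifier widths -> 1 (weights + biases).
    """
    total = 0
    for c_in, c_out, k in zip(spec.channels[:-1], spec.channels[1:],
                              spec.kernel_sizes):
        total += c_in * c_out * k * k + c_out
    widths = (spec.channels[-1],) + spec.classifier_widths + (spec.output_units,)
    for n_in, n_out in zip(widths[:-1], widths[1:]):
        total += n_in * n_out + n_out
    return total


def stage_trace(spec: ArchitectureSpec,
                input_shape: Tuple[int, int]) -> List[Tuple[Tuple[int, int], Tuple[int, int]]]:
    """Spatial extents after each conv and pool stage.

    Valid convolution shrinks each axis by k-1 and must keep extent >= 1;
    pooling halves it (floor), leaving singleton axes untouched.  Raises
    ValueError naming the first failing stage.
    """
    h, w = input_shape
    trace = []
    for i, k in enumerate(spec.kernel_sizes, start=1):
        ch, cw = h - k + 1, w - k + 1
        if ch < 1 or cw < 1:
            raise ValueError(
                f"input too small: stage {i} (conv k={k}) would have extent "
                f"{ch}x{cw}")
        h = ch // 2 if ch >= 2 else 1
        w = cw // 2 if cw >= 2 else 1
        trace.append(((ch, cw), (h, w)))
    return trace


class Network:
    """A built detector network with explicit forward/backward passes.

    Weight initialisation is controlled by ``seed``; dropout is active only
    when ``training=True`` is passed through the forward pass.
    """

    def __init__(self, spec: ArchitectureSpec, input_shape: Tuple[int, int],
                 seed: int = 0):
        self.spec = spec
        self.input_shape = tuple(input_shape)
        self.trace = stage_trace(spec, input_shape)  # validates the shape
        rng = np.random.default_rng(seed)
        self.conv_stack: List[object] = []
        for c_in, c_out, k in zip(spec.channels[:-1], spec.channels[1:],
                                  spec.kernel_sizes):
            self.conv_stack += [Conv2D(c_in, c_out, k, rng), ReLU(),
                                MaxPool2(), Dropout(spec.dropout_rate)]
        self.gap = GlobalAvgPool()
        self.head: List[object] = []
        widths = (spec.channels[-1],) + spec.classifier_widths
        for n_in, n_out in zip(widths[:-1], widths[1:]):
            self.head += [Dense(n_in, n_out, rng), ReLU(),
                          Dropout(spec.dropout_rate)]
        # near-zero output head: scoring starts at the uninformative prior
        # (probability 0.5) instead of saturated logits, which keeps the
        # first optimisation steps well-scaled on correlated spectrograms
        self.head.append(Dense(widths[-1], spec.output_units, rng, scale=1e-2))
        self._layers = self.conv_stack + [self.gap] + self.head

    # -- passes ----------------------------------------------------------

    def forward_logits(self, tiles: np.ndarray, training: bool = False,
                       rng: Optional[np.random.Generator] = None) -> np.ndarray:
        x = np.asarray(tiles, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3 or x.shape[1:] != self.input_shape:
            raise ValueError(f"expected tiles of shape {self.input_shape}")
        x = x[:, None]  # one input channel
        for layer in self.conv_stack:
            x = layer.forward(x, training=training, rng=rng)
        x = self.gap.forward(x, training=training, rng=rng)
        for layer in self.head:
            x = layer.forward(x, training=training, rng=rng)
        return x[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        d = np.asarray(dlogits, dtype=np.float32)[:, None]
        for layer in reversed(self.head):
            d = layer.backward(d)
        d = self.gap.backward(d)
        for j, layer in enumerate(reversed(self.conv_stack)):
            last = j == len(self.conv_stack) - 1
            if isinstance(layer, Conv2D):
                d = layer.backward(d, need_dx=not last)
            else:
                d = layer.backward(d)

    # -- parameters ------------------------------------------------------

    def parameters(self) -> List[np.ndarray]:
        out = []
        for layer in self._layers:
            out += layer.params()
        return out

    def gradients(self) -> List[np.ndarray]:
        out = []
        for layer in self._layers:
            out += layer.grads()
        return out

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def get_weights(self) -> List[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(weights) != len(params):
            raise ValueError("weight list does not match architecture")
        for p, w in zip(params, weights):
            if p.shape != w.shape:
                raise ValueError("weight shape mismatch")
            p[...] = w

    def make_optimizer(self, lr: float = 1e-3) -> Adam:
        return Adam(self.parameters(), lr=lr)

    # -- persistence -----------------------------------------------------

    def save(self, path) -> None:
        arrays = {f"p{i}": p for i, p in enumerate(self.parameters())}
        np.savez(path, spec=self.spec.to_json(),
                 input_shape=np.asarray(self.input_shape), **arrays)

    @classmethod
    def load(cls, path) -> "Network":
        data = np.load(path, allow_pickle=False)
        spec = ArchitectureSpec.from_json(str(data["spec"]))
        net = cls(spec, tuple(int(v) for v in data["input_shape"]))
        n = len(net.parameters())
        net.set_weights([data[f"p{i}"] for i in range(n)])
        return net


def build_network(spec: ArchitectureSpec, input_shape: Tuple[int, int],
                  seed: int = 0) -> Network:
    """Build the network, rejecting input shapes any stage would collapse."""
    return Network(spec, input_shape, seed=seed)


def predict_scores(network: Network, tiles: np.ndarray,
                   norm_stats, batch_size: int = 16) -> np.ndarray:
    """Score standardized tiles in evaluation mode (dropout off).

    ``norm_stats`` (the training-split statistics) is mandatory: scoring
    unstandardized tiles is a contract violation, not a silent fallback.
    """
    if norm_stats is None:
        raise ValueError("norm_stats is required: standardize with the "
                         "training-split statistics before scoring")
    tiles = np.asarray(tiles, dtype=np.float32)
    if tiles.ndim == 2:
        tiles = tiles[None]
    x = (tiles - np.float32(norm_stats.mean)) / np.float32(norm_stats.sd)
    probs = np.empty(x.shape[0], dtype=np.float64)
    for i in range(0, x.shape[0], batch_size):
        logits = network.forward_logits(x[i:i + batch_size], training=False)
        probs[i:i + batch_size] = sigmoid(logits)
    return probs
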