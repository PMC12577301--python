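"""Sequential model container and the volumetric CNN architectures.

The 3D network is three conv(3x3x3, same padding) + ReLU + max-pool(2^3,
stride 2) blocks with 16, 32, and 64 output channels, a fully connected layer
down to 128 features, and a final head of 2 log-softmax class outputs
(classification) or a single linear unit (regression). Three pooling stages
halve every spatial dimension three times, so a D x H x W input flattens to
64 * (D/8) * (H/8) * (W/8) features.

Initialization: He-uniform for the convolutional stack, a doubled gain for
the fully connected representation layer (high-variance features shorten the
head's alignment phase), and a near-zero output head, so training starts at
the class-prior loss and the logits grow only as evidence accumulates. These
choices affect optimization speed, not the hypothesis class.
"""

from __future__ import annotations

import copy
import math

import numpy as np

from .layers import ConvND, Flatten, Linear, LogSoftmax, MaxPoolND, ReLU

__all__ = ["Sequential", "build_cnn3d", "build_cnn2d"]


class Sequential:
    def __init__(self, layers: list) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def get_params(self) -> list[dict[str, np.ndarray]]:
        return [copy.deepcopy(layer.params) for layer in self.layers]

    def set_params(self, params: list[dict[str, np.ndarray]]) -> None:
        for layer, p in zip(self.layers, params):
            layer.params = copy.deepcopy(p)

    @property
    def n_parameters(self) -> int:
        return sum(int(v.size) for layer in self.layers for v in layer.params.values())


def build_cnn3d(input_shape, task: str = "classify", seed: int = 0,
                conv_channels=(16, 32, 64), hidden_fc: int = 128) -> Sequential:
    """Build the volumetric CNN for ``classify`` (2 log-probabilities) or
    ``regress`` (1 scalar). Each spatial dimension must be a multiple of 8
    and at least 8, so the three pooling stages divide it cleanly."""
    if task not in ("classify", "regress"):
        raise ValueError(f"task must be 'classify' or 'regress', got {task!r}")
    shape = tuple(int(s) for s in input_shape)
    if len(shape) != 3:
        raise ValueError(f"input_shape must be 3D, got {shape}")
    if any(s < 8 or s % 8 for s in shape):
        raise ValueError(f"each spatial dim must be a multiple of 8 and >= 8, got {shape}")
    rng = np.random.default_rng(seed)
    layers: list = []
    in_ch = 1
    for out_ch in conv_channels:
        layers += [ConvND(in_ch, out_ch, ndim=3, rng=rng), ReLU(), MaxPoolND(ndim=3)]
        in_ch = out_ch
    flat = conv_channels[-1] * int(np.prod([s // 8 for s in shape]))
    layers += [Flatten(), Linear(flat, hidden_fc, rng, init_gain=2.0 * math.sqrt(6.0)), ReLU()]
    if task == "classify":
        layers += [Linear(hidden_fc, 2, rng, init_gain=0.02), LogSoftmax()]
    else:
        layers += [Linear(hidden_fc, 1, rng, init_gain=0.02)]
    model = Sequential(layers)
    model.input_shape = shape
    model.task = task
    model.flatten_length = flat
    return model


def build_cnn2d(input_shape, task: str = "classify", seed: int = 0,
                conv_channels=(16, 32), hidden_fc: int = 128) -> Sequential:
    """2D analog used as a baseline: two conv-pool blocks on a single slice."""
    if task != "classify":
        raise ValueError("the 2D baseline is classification-only")
    shape = tuple(int(s) for s in input_shape)
    if len(shape) != 2:
        raise ValueError(f"input_shape must be 2D, got {shape}")
    if any(s < 4 or s % 4 for s in shape):
        raise ValueError(f"each spatial dim must be a multiple of 4 and >= 4, got {shape}")
    rng = np.random.default_rng(seed)
    layers: list = []
    in_ch = 1
    for out_ch in conv_channels:
        layers += [ConvND(in_ch, out_ch, ndim=2, rng=rng), ReLU(), MaxPoolND(ndim=2)]
        in_ch = out_ch
    flat = conv_channels[-1] * int(np.prod([s // 4 for s in shape]))
    layers += [Flatten(), Linear(flat, hidden_fc, rng, init_gain=2.0 * math.sqrt(6.0)), ReLU(),
               Linear(hidden_fc, 2, rng, init_gain=0.02), LogSoftmax()]
    model = Sequential(layers)
    model.input_shape = shape
    model.task = task
    model.flatten_length = flat
    return model
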