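"""Promoter CNN configuration and construction.

The network maps a C x L input (C in {1, 4, 5}: ATAC-only, DNA-only,
DNA+ATAC) to a single expression probability. The default architecture is
Xpresso-like with an extra dense layer: two conv blocks (128 filters x
width 6 -> max-pool 4; 32 filters x width 9 -> max-pool 4), dense layers
256 and 64 with dropout 0.1 after each, and a sigmoid output — GEx is a
proportion, so the head is bounded in (0, 1). Every width is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn

CHANNEL_MODES = {"atac_only": [4], "dna_only": [0, 1, 2, 3], "dna_atac": [0, 1, 2, 3, 4]}


@dataclass
class ModelConfig:
    input_channels: int = 5
    input_length: int = 2000
    conv_specs: tuple = ((128, 6, 4), (32, 9, 4))  # (n_filters, kernel, pool)
    dense_sizes: tuple = (256, 64)
    dropout: float = 0.1
    output_activation: str = "sigmoid"

    def __post_init__(self):
        if self.input_channels not in (1, 4, 5):
            raise ValueError("input_channels must be 1, 4 or 5")
        if self.output_activation not in ("sigmoid", "linear"):
            raise ValueError("output_activation must be 'sigmoid' or 'linear'")

    def flattened_size(self) -> int:
        """Length x channels entering the first dense layer (validates the
        conv/pool stack against the input length)."""
        length = self.input_length
        for n_filters, kernel, pool in self.conv_specs:
            if length - kernel + 1 < 1:
                raise ValueError(
                    f"kernel width {kernel} exceeds remaining length {length}"
                )
            length = (length - kernel + 1) // pool
            if length < 1:
                raise ValueError(f"pool width {pool} collapses the input below length 1")
        return length * self.conv_specs[-1][0] if self.conv_specs else length * self.input_channels

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["conv_specs"] = tuple(tuple(s) for s in d["conv_specs"])
        d["dense_sizes"] = tuple(d["dense_sizes"])
        return cls(**d)


def build_model(config: ModelConfig, seed: int) -> nn.Sequential:
    """Construct the CNN with deterministic seeded initialization."""
    config.flattened_size()  # validate geometry up front
    rng = np.random.default_rng(seed)
    layers = []
    in_ch = config.input_channels
    for n_filters, kernel, pool in config.conv_specs:
        layers.append(nn.Conv1d(in_ch, n_filters, kernel, rng))
        layers.append(nn.ReLU())
        layers.append(nn.MaxPool1d(pool))
        in_ch = n_filters
    layers.append(nn.Flatten())
    in_features = config.flattened_size()
    for size in config.dense_sizes:
        layers.append(nn.Dense(in_features, size, rng))
        layers.append(nn.ReLU())
        layers.append(nn.Dropout(config.dropout, rng))
        in_features = size
    layers.append(nn.Dense(in_features, 1, rng))
    if config.output_activation == "sigmoid":
        layers.append(nn.Sigmoid())
    return nn.Sequential(layers)


def count_parameters(model: nn.Sequential) -> int:
    """Total trainable scalar parameters.

    Adding one input channel adds exactly ``n_filters_1 x kernel_1``
    parameters (the extra first-layer slice); nothing downstream changes.
    """
    return model.count_parameters()


def predict(model: nn.Sequential, x: np.ndarray) -> np.ndarray:
    """Inference on (N, C, L) samples -> (N,) predictions."""
    x = np.asarray(x)
    first_conv = next(l for l in model.layers if isinstance(l, nn.Conv1d))
    if x.shape[1] != first_conv.in_channels:
        raise ValueError(
            f"input has {x.shape[1]} channels, model expects {first_conv.in_channels}"
        )
    return model.predict(x)


def ablate_channels(x: np.ndarray, mode: str) -> np.ndarray:
    """Select channel rows of a 5-channel array (…, 5, L) by ablation mode."""
    if mode not in CHANNEL_MODES:
        raise ValueError(f"unknown ablation mode {mode!r}; valid: {sorted(CHANNEL_MODES)}")
    x = np.asarray(x)
    axis = x.ndim - 2
    if x.shape[axis] != 5:
        raise ValueError(f"expected 5 channels, got {x.shape[axis]}")
    return np.take(x, CHANNEL_MODES[mode], axis=axis)


def describe(config: ModelConfig, seed: int = 0) -> str:
    """Layer table with output shapes and parameter counts."""
    model = build_model(config, seed)
    lines = [f"{'layer':<12}{'output shape':<20}{'params':>10}"]
    length, ch = config.input_length, config.input_channels
    total = 0
    for layer in model.layers:
        n = sum(v.size for v in layer.params.values())
        total += n
        if isinstance(layer, nn.Conv1d):
            length = layer.out_length(length)
            ch = layer.out_channels
            shape = f"({ch}, {length})"
        elif isinstance(layer, nn.MaxPool1d):
            length = layer.out_length(length)
            shape = f"({ch}, {length})"
        elif isinstance(layer, nn.Flatten):
            shape = f"({ch * length},)"
        elif isinstance(layer, nn.Dense):
            shape = f"({layer.params['W'].shape[0]},)"
        else:
            shape = "-"
        lines.append(f"{type(layer).__name__:<12}{shape:<20}{n:>10}")
    lines.append(f"{'total':<32}{total:>10}")
    return "\n".join(lines)
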