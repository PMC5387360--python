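"""Convolutional DNA module.

Motif-scanning convolutions over a one-hot sequence window centred on the
target CpG, interleaved with non-overlapping max pooling, followed by one
fully connected ReLU layer that models motif interactions.  The first-layer
filters act as learned position weight matrices; they are what the motif
interpretation suite reads out.

The convolution is "valid" (no padding) and scans the forward strand only;
there is no reverse-complement filter tying.  Pooling drops the
width-mod-P remainder positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Conv1D, Dense, Module


@dataclass
class DnaNetConfig:
    """Architecture of the DNA module.

    Defaults: two conv–pool pairs, 128 length-11 filters then 256 length-3
    filters, pool size 4, a 128-unit fully connected layer.  All of it is
    configurable; small test-scale models just shrink these numbers.
    """

    n_conv_pool_pairs: int = 2
    filters_per_layer: list[int] = field(default_factory=lambda: [128, 256])
    filter_lengths: list[int] = field(default_factory=lambda: [11, 3])
    pool_size: int = 4
    fc_units: int = 128
    dropout_rate: float = 0.0

    def __post_init__(self):
        if len(self.filters_per_layer) != self.n_conv_pool_pairs:
            raise ValueError("filters_per_layer length must equal n_conv_pool_pairs")
        if len(self.filter_lengths) != self.n_conv_pool_pairs:
            raise ValueError("filter_lengths length must equal n_conv_pool_pairs")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")


def conv_activations(window: np.ndarray, weights: np.ndarray,
                     bias: np.ndarray | None = None) -> np.ndarray:
    """ReLU activations of a filter bank on a single one-hot window.

    ``window``: (L_win, 4); ``weights``: (F, L, 4); returns (F, L_win−L+1),
    a[f, i] = ReLU(b_f + Σ_l Σ_d w[f, l, d] · s[i+l, d]) for a valid scan.
    """
    F, L, D = weights.shape
    if L > window.shape[0]:
        raise ValueError(f"filter length {L} exceeds window length {window.shape[0]}")
    if bias is None:
        bias = np.zeros(F)
    out = ad.conv1d(Tensor(window[None]), Tensor(weights), Tensor(bias)).data[0]
    return np.maximum(out.T, 0.0)


def max_pool(a: np.ndarray, P: int) -> np.ndarray:
    """Non-overlapping max pooling of an (F, W) activation matrix.

    Output width is floor(W / P); remainder positions are dropped.
    """
    if P < 1:
        raise ValueError("P must be >= 1")
    F, W = a.shape
    n = W // P
    return a[:, : n * P].reshape(F, n, P).max(axis=2)


class DnaNet(Module):
    """The DNA module body: conv–pool stack plus fully connected feature layer."""

    def __init__(self, rng: np.random.Generator, cfg: DnaNetConfig,
                 L_win: int, name: str = "dna"):
        self.cfg = cfg
        self.L_win = L_win
        self.name = name
        self.conv_layers: list[Conv1D] = []
        depth = 4
        width = L_win
        for i in range(cfg.n_conv_pool_pairs):
            F, L = cfg.filters_per_layer[i], cfg.filter_lengths[i]
            self.conv_layers.append(Conv1D(rng, F, L, depth, f"{name}/conv{i}"))
            width = (width - L + 1) // cfg.pool_size
            if width < 1:
                raise ValueError("window too short for the configured conv/pool stack")
            depth = F
        self.flat_dim = width * depth
        self.fc = Dense(rng, self.flat_dim, cfg.fc_units, f"{name}/fc",
                        activation="relu")

    def forward(self, windows: Tensor, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """(B, L_win, 4) one-hot → (B, fc_units) features.

        Dropout (after each pooling layer and after the FC layer) is active
        only when ``training`` is set; inference is deterministic.
        """
        h = windows
        for conv in self.conv_layers:
            h = ad.relu(conv(h))
            h = ad.max_pool1d(h, self.cfg.pool_size)
            if training and self.cfg.dropout_rate > 0:
                h = ad.dropout(h, self.cfg.dropout_rate, rng)
        B = h.data.shape[0]
        h = ad.reshape(h, (B, self.flat_dim))
        h = self.fc(h)
        if training and self.cfg.dropout_rate > 0:
            h = ad.dropout(h, self.cfg.dropout_rate, rng)
        return h

    def first_layer_activations(self, windows: np.ndarray) -> np.ndarray:
        """ReLU activations of the first conv layer, shape (B, W_out, F)."""
        conv = self.conv_layers[0]
        out = ad.conv1d(Tensor(windows), conv.W, conv.b).data
        return np.maximum(out, 0.0)


def dna_forward(window: np.ndarray, net: DnaNet) -> np.ndarray:
    """Feature vector of one window through a DnaNet (inference mode)."""
    return net.forward(Tensor(window[None])).data[0]
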