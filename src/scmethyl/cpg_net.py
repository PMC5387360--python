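"""CpG module: per-cell embedding plus a bidirectional GRU over cells.

Each cell contributes a 4K-dimensional neighbour-context vector (K observed
CpG states and normalised distances on each side of the target site).  A
fully connected ReLU embedding models interactions between states and
distances within a cell; a bidirectional gated recurrent network then scans
the embedded cells — forward and backward with independent parameters, both
from zero initial state — and the two final hidden states are concatenated.
The output size (2H) is independent of the number of cells T.

Cells are scanned in a fixed order (sorted cell_id).  A biGRU with untied
parameters is not literally order-invariant; the fixed ordering keeps
results reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Dense, GRUCell, Module


@dataclass
class CpgNetConfig:
    embed_units: int = 256   # E: per-cell embedding width
    hidden_units: int = 256  # H: GRU hidden state width (output is 2H)
    dropout_rate: float = 0.0


def embed(x_t: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """ReLU(W · x_t + b) for a single cell's context vector."""
    return np.maximum(W @ x_t + b, 0.0)


def gru_step(x_t: np.ndarray, h_prev: np.ndarray, params: dict[str, np.ndarray]
             ) -> np.ndarray:
    """One GRU update written out explicitly (numpy, single vector).

    r = σ(W_rx x + W_rh h + b_r); u likewise;
    c = tanh(W_cx x + W_ch (r ⊙ h) + b_c); h' = (1 − u) ⊙ h + u ⊙ c.
    ``params`` keys: W_rx, W_rh, b_r, W_ux, W_uh, b_u, W_cx, W_ch, b_c,
    with input-side matrices shaped (E, H).
    """
    def sig(z):
        return 1.0 / (1.0 + np.exp(-z))

    r = sig(x_t @ params["W_rx"] + h_prev @ params["W_rh"] + params["b_r"])
    u = sig(x_t @ params["W_ux"] + h_prev @ params["W_uh"] + params["b_u"])
    c = np.tanh(x_t @ params["W_cx"] + (r * h_prev) @ params["W_ch"] + params["b_c"])
    return (1.0 - u) * h_prev + u * c


class CpgNet(Module):
    """Embedding + bidirectional GRU; output (B, 2H)."""

    def __init__(self, rng: np.random.Generator, cfg: CpgNetConfig,
                 context_dim: int, name: str = "cpg"):
        self.cfg = cfg
        self.name = name
        self.embedding = Dense(rng, context_dim, cfg.embed_units,
                               f"{name}/embed", activation="relu")
        self.gru_fwd = GRUCell(rng, cfg.embed_units, cfg.hidden_units,
                               f"{name}/gru_fwd")
        self.gru_bwd = GRUCell(rng, cfg.embed_units, cfg.hidden_units,
                               f"{name}/gru_bwd")

    def forward(self, contexts: Tensor, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """(B, T, 4K) contexts → (B, 2H) features."""
        B, T, _ = contexts.data.shape
        if T < 1:
            raise ValueError("need at least one cell")
        embedded = [self.embedding(contexts[:, t, :]) for t in range(T)]
        if training and self.cfg.dropout_rate > 0:
            embedded = [ad.dropout(e, self.cfg.dropout_rate, rng) for e in embedded]
        H = self.cfg.hidden_units
        h_f = Tensor(np.zeros((B, H)))
        for t in range(T):
            h_f = self.gru_fwd.step(embedded[t], h_f)
        h_b = Tensor(np.zeros((B, H)))
        for t in reversed(range(T)):
            h_b = self.gru_bwd.step(embedded[t], h_b)
        out = ad.concat([h_f, h_b], axis=1)
        if training and self.cfg.dropout_rate > 0:
            out = ad.dropout(out, self.cfg.dropout_rate, rng)
        return out


def bigru_encode(contexts: np.ndarray, net: CpgNet) -> np.ndarray:
    """Encode one site's (T, 4K) cell contexts to a 2H vector (inference)."""
    return net.forward(Tensor(contexts[None])).data[0]
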