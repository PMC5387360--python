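"""Layers, initialisation and optimisation on top of :mod:`scmethyl.autodiff`.

Parameters are named hierarchically (``"dna/conv0/W"``) so that models can be
assembled from pre-trained modules, parameter groups can be frozen for
fine-tuning, and files round-trip exactly.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Param(Tensor):
    """A trainable tensor with a stable name and freeze/bias flags."""

    __slots__ = ("name", "is_bias", "trainable")

    def __init__(self, data, name: str, is_bias: bool = False, trainable: bool = True):
        super().__init__(data, requires_grad=True)
        self.name = name
        self.is_bias = is_bias
        self.trainable = trainable


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Module:
    """Base class: a named collection of parameters and sub-modules."""

    def params(self) -> dict[str, Param]:
        out: dict[str, Param] = {}
        for attr in vars(self).values():
            if isinstance(attr, Param):
                out[attr.name] = attr
            elif isinstance(attr, Module):
                out.update(attr.params())
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        out.update(item.params())
                    elif isinstance(item, Param):
                        out[item.name] = item
        return out

    def zero_grad(self) -> None:
        for p in self.params().values():
            p.zero_grad()

    def set_trainable(self, trainable: bool, prefix: str = "") -> None:
        for name, p in self.params().items():
            if name.startswith(prefix):
                p.trainable = trainable

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.params().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.params()
        for name, arr in state.items():
            if name in params:
                if params[name].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {name}: "
                                     f"{params[name].data.shape} vs {arr.shape}")
                params[name].data = np.array(arr, dtype=np.float64)


class Dense(Module):
    """Fully connected layer ``x @ W + b`` with optional activation."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int,
                 name: str, activation: str | None = None):
        self.W = Param(glorot_uniform(rng, (n_in, n_out), n_in, n_out), f"{name}/W")
        self.b = Param(np.zeros(n_out), f"{name}/b", is_bias=True)
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        z = (x @ self.W) + self.b
        if self.activation == "relu":
            return ad.relu(z)
        if self.activation == "sigmoid":
            return ad.sigmoid(z)
        if self.activation == "tanh":
            return ad.tanh(z)
        return z


class Conv1D(Module):
    """Valid convolution over one-hot sequence, ReLU applied by the caller."""

    def __init__(self, rng: np.random.Generator, n_filters: int, length: int,
                 depth: int, name: str):
        fan_in = length * depth
        self.W = Param(glorot_uniform(rng, (n_filters, length, depth),
                                      fan_in, n_filters), f"{name}/W")
        self.b = Param(np.zeros(n_filters), f"{name}/b", is_bias=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv1d(x, self.W, self.b)


class GRUCell(Module):
    """Gated recurrent unit with reset/update gates and tanh candidate state."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_hidden: int, name: str):
        def w(nm, shape, fi, fo):
            return Param(glorot_uniform(rng, shape, fi, fo), f"{name}/{nm}")

        E, H = n_in, n_hidden
        self.W_rx = w("W_rx", (E, H), E, H)
        self.W_rh = w("W_rh", (H, H), H, H)
        self.b_r = Param(np.zeros(H), f"{name}/b_r", is_bias=True)
        self.W_ux = w("W_ux", (E, H), E, H)
        self.W_uh = w("W_uh", (H, H), H, H)
        self.b_u = Param(np.zeros(H), f"{name}/b_u", is_bias=True)
        self.W_cx = w("W_cx", (E, H), E, H)
        self.W_ch = w("W_ch", (H, H), H, H)
        self.b_c = Param(np.zeros(H), f"{name}/b_c", is_bias=True)
        self.n_hidden = H

    def step(self, x: Tensor, h_prev: Tensor) -> Tensor:
        r = ad.sigmoid((x @ self.W_rx) + (h_prev @ self.W_rh) + self.b_r)
        u = ad.sigmoid((x @ self.W_ux) + (h_prev @ self.W_uh) + self.b_u)
        c = ad.tanh((x @ self.W_cx) + (ad.mul(r, h_prev) @ self.W_ch) + self.b_c)
        one = Tensor(1.0)
        return ad.add(ad.mul(one - u, h_prev), ad.mul(u, c))


class Adam:
    """Adam optimiser over a parameter dict; skips frozen parameters."""

    def __init__(self, params: dict[str, Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for name, p in self.params.items():
            if not p.trainable or p.grad is None:
                continue
            g = p.grad
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            mhat = self.m[name] / (1 - b1 ** self.t)
            vhat = self.v[name] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()


# -- flat-parameter helpers (finite-difference checks, tests) -------------

def get_flat_params(params: dict[str, Param],
                    names: Iterable[str] | None = None) -> np.ndarray:
    keys = sorted(params) if names is None else list(names)
    return np.concatenate([params[k].data.ravel() for k in keys])


def set_flat_params(params: dict[str, Param], flat: np.ndarray,
                    names: Iterable[str] | None = None) -> None:
    keys = sorted(params) if names is None else list(names)
    offset = 0
    for k in keys:
        n = params[k].data.size
        params[k].data = flat[offset:offset + n].reshape(params[k].data.shape).copy()
        offset += n


def get_flat_grads(params: dict[str, Param],
                   names: Iterable[str] | None = None) -> np.ndarray:
    keys = sorted(params) if names is None else list(names)
    out = []
    for k in keys:
        g = params[k].grad
        out.append(np.zeros(params[k].data.size) if g is None else g.ravel())
    return np.concatenate(out)
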