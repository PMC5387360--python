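"""Minimal reverse-mode automatic differentiation over numpy arrays.

The model in this package is small enough that a dedicated tensor engine —
a :class:`Tensor` wrapping an ``ndarray`` plus a topologically sorted
backward pass — is both sufficient and fully transparent.  All arithmetic
is float64; gradients are exact up to floating point, which the test suite
verifies against central finite differences.

Only the operations the networks need are implemented: broadcasting
arithmetic, matmul (including batched), the ReLU/sigmoid/tanh
non-linearities, log/exp/pow, clip, sum/mean, concatenate, reshape,
basic indexing, a valid 1-D convolution over one-hot sequence and
non-overlapping max pooling.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import expit


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -- graph plumbing ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64, copy=True)
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node through the graph."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator helpers -------------------------------------------------

    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __radd__(self, other):
        return add(_as_tensor(other), self)

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), _as_tensor(-1.0)))

    def __rsub__(self, other):
        return add(_as_tensor(other), mul(self, _as_tensor(-1.0)))

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __rmul__(self, other):
        return mul(_as_tensor(other), self)

    def __neg__(self):
        return mul(self, _as_tensor(-1.0))

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def __pow__(self, exponent: float):
        return power(self, exponent)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents: Sequence[Tensor], backward) -> Tensor:
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, parents=tuple(parents),
                  backward=backward if req else None)


# -- primitive operations -------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    out = _make(out_data, (a, b), None)
    out._backward = bwd if out.requires_grad else None
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    out = _make(out_data, (a, b), None)
    out._backward = bwd if out.requires_grad else None
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def bwd(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.data.shape))

    out = _make(out_data, (a, b), None)
    out._backward = bwd if out.requires_grad else None
    return out


def power(a: Tensor, exponent: float) -> Tensor:
    out_data = a.data ** exponent

    def bwd(g):
        a._accumulate(g * exponent * a.data ** (exponent - 1.0))

    out = _make(out_data, (a,), None)
    out._backward = bwd if out.requires_grad else None
    return out


def relu(a: Tensor) -> Tensor:
    out_data = np.maximum(a.data, 0.0)

    def bwd(g):
        a._accumulate(g * (a.data > 0.0))

    out = _make(out_data, (a,), None)
    out._backward = bwd if out.requires_grad else None
    return out


def sigmoid(a: Tensor) -> Tensor:
    out_data = expit(a.data)

    def bwd(g):
        a._accumulate(g * out_data * (1.0 - out_data))

    out = _make(out_data, (a,), None)
    out._backward = bwd if out.requires_grad else None
    return out


def tanh(a: Tensor) -> Tensor:
    out_data = np.tanh(a.data)

    def bwd(g):
        a._accumulate(g * (1.0 - out_data * out_data))

    out = _make(out_data, (a,), None)
    out._backward = bwd if out.requires_grad else None
    return out


def log(a: Tensor) -> Tensor:
    out_data = np.log(a.data)

    def bwd(g):
        a._accumulate(g / a.data)

    out = _make(out_data, (a,), None)
    out._backward = bwd if out.requires_grad else None
    return out


def exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)

    def bwd(g):
        a._accumulate(g * out_data)

    out = _make(out_data, (a,), None)
    out._backward = bwd if out.requires_grad else None
    return out


def clip(a: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values to [lo, hi]; gradient passes through inside the bounds."""
    out_data = np.clip(a.data, lo, hi)
    mask = (a.data >= lo) & (a.data <= hi)

    def bwd(g):
        a._accumulate(g * mask)

    out = _make(out_data, (a,), None)
    out._backward = bwd if out.requires_grad else None
    return out


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bwd(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            for ax in sorted(a2 % a.data.ndim for a2 in axes):
                g = np.expand_dims(g, ax)
        a._accumulate(np.broadcast_to(g, a.data.shape).copy())

    out = _make(out_data, (a,), None)
    out._backward = bwd if out.requires_grad else None
    return out


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis=axis, keepdims=keepdims), _as_tensor(1.0 / float(n)))


def reshape(a: Tensor, shape) -> Tensor:
    out_data = a.data.reshape(shape)

    def bwd(g):
        a._accumulate(g.reshape(a.data.shape))

    out = _make(out_data, (a,), None)
    out._backward = bwd if out.requires_grad else None
    return out


def getitem(a: Tensor, idx) -> Tensor:
    out_data = a.data[idx]

    def bwd(g):
        full = np.zeros_like(a.data)
        np.add.at(full, idx, g)
        a._accumulate(full)

    out = _make(out_data, (a,), None)
    out._backward = bwd if out.requires_grad else None
    return out


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    ts = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out = _make(out_data, tuple(ts), None)
    out._backward = bwd if out.requires_grad else None
    return out


# -- sequence-model operations -------------------------------------------

def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Valid 1-D convolution of one-hot sequence with a filter bank.

    ``x``: (B, W_in, D) input; ``w``: (F, L, D) filters; ``b``: (F,) biases.
    Returns pre-activation tensor of shape (B, W_in − L + 1, F).  Implemented
    with an im2col expansion so both passes are single matmuls.
    """
    B, W_in, D = x.data.shape
    F, L, Dw = w.data.shape
    if Dw != D:
        raise ValueError(f"filter depth {Dw} != input depth {D}")
    if L > W_in:
        raise ValueError(f"filter length {L} exceeds input length {W_in}")
    W_out = W_in - L + 1
    # (B, W_out, L, D) windows via stride tricks; contiguous copy for matmul.
    cols = np.lib.stride_tricks.sliding_window_view(x.data, L, axis=1)
    cols = np.ascontiguousarray(cols.transpose(0, 1, 3, 2)).reshape(B, W_out, L * D)
    wf = w.data.reshape(F, L * D)
    out_data = cols @ wf.T + b.data

    def bwd(g):
        if w.requires_grad:
            gw = g.reshape(-1, F).T @ cols.reshape(-1, L * D)
            w._accumulate(gw.reshape(F, L, D))
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 1)))
        if x.requires_grad:
            dcols = (g @ wf).reshape(B, W_out, L, D)
            dx = np.zeros_like(x.data)
            for l in range(L):
                dx[:, l:l + W_out, :] += dcols[:, :, l, :]
            x._accumulate(dx)

    out = _make(out_data, (x, w, b), None)
    out._backward = bwd if out.requires_grad else None
    return out


def max_pool1d(x: Tensor, pool_size: int) -> Tensor:
    """Non-overlapping max pooling over the position axis of (B, W, F).

    Positions past the last full pool (the width-mod-P remainder) are dropped.
    """
    if pool_size < 1:
        raise ValueError("pool size must be >= 1")
    B, W, F = x.data.shape
    n = W // pool_size
    trimmed = x.data[:, : n * pool_size, :].reshape(B, n, pool_size, F)
    arg = trimmed.argmax(axis=2)
    out_data = np.take_along_axis(trimmed, arg[:, :, None, :], axis=2)[:, :, 0, :]

    def bwd(g):
        dtr = np.zeros((B, n, pool_size, F))
        np.put_along_axis(dtr, arg[:, :, None, :], g[:, :, None, :], axis=2)
        dx = np.zeros_like(x.data)
        dx[:, : n * pool_size, :] = dtr.reshape(B, n * pool_size, F)
        x._accumulate(dx)

    out = _make(out_data, (x,), None)
    out._backward = bwd if out.requires_grad else None
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; call only in training mode."""
    if rate <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= rate) / (1.0 - rate)
    return mul(x, Tensor(mask))
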