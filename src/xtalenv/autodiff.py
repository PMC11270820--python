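"""Minimal reverse-mode automatic differentiation on NumPy float64 arrays.

Provides exactly the primitives the two classifiers need: broadcasted
arithmetic, matmul, GeLU, layer norm, log-softmax, dropout, row gathering
and segment reductions (sum / max) for graph message passing and
per-molecule aggregation.  Gradients are checked against central finite
differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.special import erf

__all__ = [
    "Tensor",
    "tensor",
    "parameter",
    "matmul",
    "gelu",
    "layer_norm",
    "log_softmax",
    "dropout",
    "gather_rows",
    "segment_sum",
    "segment_max",
    "segment_softmax",
    "concat",
    "pick",
    "Adam",
]


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data: np.ndarray,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    # -- graph traversal ----------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
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
        for node in topo:
            node.grad = None  # lazily materialized by _accum
        self.grad = np.array(grad, dtype=float).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        # single-use graph: drop closures and edges so everything is freed
        # promptly by reference counting
        for node in topo:
            node._backward = None
            node._parents = ()

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other: "Tensor | float") -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g: np.ndarray) -> None:
            _accum(self, _unbroadcast(g, self.data.shape))
            _accum(other, _unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other: "Tensor | float") -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g: np.ndarray) -> None:
            _accum(self, _unbroadcast(g * other.data, self.data.shape))
            _accum(other, _unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * (-1.0)

    def __sub__(self, other: "Tensor | float") -> "Tensor":
        return self + (-_as_tensor(other))

    def __rsub__(self, other: float) -> "Tensor":
        return _as_tensor(other) + (-self)

    def __truediv__(self, other: "Tensor | float") -> "Tensor":
        return self * _as_tensor(other).reciprocal()

    def reciprocal(self) -> "Tensor":
        out = Tensor(1.0 / self.data, parents=(self,))

        def bw(g: np.ndarray) -> None:
            _accum(self, -g / (self.data**2))

        out._backward = bw
        return out

    def exp(self) -> "Tensor":
        data = np.exp(self.data)
        out = Tensor(data, parents=(self,))

        # capture the array, not `out`: a closure referencing `out` creates
        # a reference cycle that delays freeing of large graphs
        def bw(g: np.ndarray) -> None:
            _accum(self, g * data)

        out._backward = bw
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), parents=(self,))

        def bw(g: np.ndarray) -> None:
            _accum(self, g / self.data)

        out._backward = bw
        return out

    def sum(self, axis: int | None = None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g: np.ndarray) -> None:
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            _accum(self, np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis: int | None = None) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)

    def reshape(self, *shape: int) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def bw(g: np.ndarray) -> None:
            _accum(self, g.reshape(self.data.shape))

        out._backward = bw
        return out

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())


def _as_tensor(x: "Tensor | float | np.ndarray") -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        # may alias g; never mutated in place (second accumulation below
        # allocates), and backward closures do not reuse g after _accum
        t.grad = g
    else:
        t.grad = t.grad + g


def _scatter_matrix(idx: np.ndarray, n_rows: int) -> sp.csr_matrix:
    """Sparse indicator S with S[idx[e], e] = 1; S @ g scatter-adds g."""
    e = len(idx)
    return sp.csr_matrix(
        (np.ones(e), (idx, np.arange(e))), shape=(n_rows, e)
    )


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def tensor(data: np.ndarray | float) -> Tensor:
    return Tensor(np.asarray(data, dtype=float))


def parameter(data: np.ndarray) -> Tensor:
    return Tensor(np.asarray(data, dtype=float), requires_grad=True)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, parents=(a, b))

    def bw(g: np.ndarray) -> None:
        _accum(a, g @ b.data.T)
        _accum(b, a.data.T @ g)

    out._backward = bw
    return out


_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) GeLU."""
    cdf = 0.5 * (1.0 + erf(x.data / _SQRT2))
    out = Tensor(x.data * cdf, parents=(x,))

    def bw(g: np.ndarray) -> None:
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * x.data**2)
        _accum(x, g * (cdf + x.data * pdf))

    out._backward = bw
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis with learnable affine."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = Tensor(xhat * gamma.data + beta.data, parents=(x, gamma, beta))

    def bw(g: np.ndarray) -> None:
        _accum(gamma, _unbroadcast(g * xhat, gamma.data.shape))
        _accum(beta, _unbroadcast(g, beta.data.shape))
        gx = g * gamma.data
        n = x.data.shape[-1]
        dx = (
            gx - gx.mean(axis=-1, keepdims=True)
            - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
        ) * inv
        _accum(x, dx)
        del n

    out._backward = bw
    return out


def log_softmax(x: Tensor) -> Tensor:
    """Row-wise log-softmax (last axis)."""
    m = x.data.max(axis=-1, keepdims=True)
    z = x.data - m
    lse = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    ls = z - lse
    out = Tensor(ls, parents=(x,))

    def bw(g: np.ndarray) -> None:
        _accum(x, g - np.exp(ls) * g.sum(axis=-1, keepdims=True))

    out._backward = bw
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when ``rng`` is None (inference)."""
    if rng is None or p <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p) / (1.0 - p)
    out = Tensor(x.data * mask, parents=(x,))

    def bw(g: np.ndarray) -> None:
        _accum(x, g * mask)

    out._backward = bw
    return out


def gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx, dtype=int)
    out = Tensor(x.data[idx], parents=(x,))

    def bw(g: np.ndarray) -> None:
        _accum(x, _scatter_matrix(idx, x.data.shape[0]) @ g)

    out._backward = bw
    return out


def segment_sum(x: Tensor, seg: np.ndarray, n_segments: int) -> Tensor:
    seg = np.asarray(seg, dtype=int)
    out = Tensor(_scatter_matrix(seg, n_segments) @ x.data, parents=(x,))

    def bw(g: np.ndarray) -> None:
        _accum(x, g[seg])

    out._backward = bw
    return out


def segment_max(x: Tensor, seg: np.ndarray, n_segments: int) -> Tensor:
    """Per-segment channel-wise maximum.

    Gradient is split evenly among tied maxima (a valid subgradient).
    Segments must be non-empty.
    """
    seg = np.asarray(seg, dtype=int)
    data = np.full((n_segments,) + x.data.shape[1:], -np.inf)
    np.maximum.at(data, seg, x.data)
    if np.any(~np.isfinite(data)):
        raise ValueError("segment_max over an empty segment")
    out = Tensor(data, parents=(x,))

    def bw(g: np.ndarray) -> None:
        mask = x.data == data[seg]
        counts = _scatter_matrix(seg, len(data)) @ mask.astype(float)
        _accum(x, mask * (g / counts)[seg])

    out._backward = bw
    return out


def segment_softmax(scores: Tensor, seg: np.ndarray, n_segments: int) -> Tensor:
    """Softmax of 1-D ``scores`` within each segment (attention weights).

    The per-segment max shift is treated as a constant (its gradient
    cancels analytically).
    """
    seg = np.asarray(seg, dtype=int)
    m = np.full(n_segments, -np.inf)
    np.maximum.at(m, seg, scores.data)
    shifted = scores - Tensor(m[seg])
    e = shifted.exp()
    denom = segment_sum(e, seg, n_segments)
    return e * gather_rows(denom, seg).reciprocal()


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, g[tuple(sl)])

    out._backward = bw
    return out


def pick(x: Tensor, rows: np.ndarray, cols: np.ndarray) -> Tensor:
    """x[rows, cols] as a 1-D tensor (used for NLL loss)."""
    rows = np.asarray(rows, dtype=int)
    cols = np.asarray(cols, dtype=int)
    out = Tensor(x.data[rows, cols], parents=(x,))

    def bw(g: np.ndarray) -> None:
        scatter = np.zeros_like(x.data)
        np.add.at(scatter, (rows, cols), g)
        _accum(x, scatter)

    out._backward = bw
    return out


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
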