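"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains a transformer encoder from scratch on CPU; this module
provides the small tensor/graph machinery that training needs (broadcasted
arithmetic, batched matmul, reductions, softmax/log-softmax, gather-style
indexing) and nothing more.  Gradients are accumulated by a topological
backward pass; correctness is checked against finite differences in the
test suite.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import erf

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._parents = tuple(parents) if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- graph ------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=np.result_type(self.data, np.float64)
                                      if self.data.dtype.kind != "f" else self.data.dtype)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar outputs")
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data
        req = self.requires_grad or other.requires_grad
        if not (req and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))
        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data
        req = self.requires_grad or other.requires_grad
        if not (req and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * (as_tensor(other) ** -1.0)

    def __rtruediv__(self, other):
        return as_tensor(other) * (self ** -1.0)

    def __pow__(self, p: float):
        out_data = self.data ** p
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,))

        def bwd(g):
            self._accumulate(g * p * self.data ** (p - 1.0))
        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data
        req = self.requires_grad or other.requires_grad
        if not (req and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self, other))

        def bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))
        out._backward = bwd
        return out

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,))
        src_shape = self.shape

        def bwd(g):
            self._accumulate(g.reshape(src_shape))
        out._backward = bwd
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out_data = np.transpose(self.data, axes or None)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,))
        if axes:
            inv = np.argsort(axes)
        else:
            inv = tuple(reversed(range(self.ndim)))

        def bwd(g):
            self._accumulate(np.transpose(g, inv))
        out._backward = bwd
        return out

    def __getitem__(self, idx):
        out_data = self.data[idx]
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)
        out._backward = bwd
        return out

    # -- reductions & elementwise ----------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,))

        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.shape).copy())
        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def exp(self):
        out_data = np.exp(self.data)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,))

        def bwd(g):
            self._accumulate(g * out_data)
        out._backward = bwd
        return out

    def log(self):
        out_data = np.log(self.data)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,))

        def bwd(g):
            self._accumulate(g / self.data)
        out._backward = bwd
        return out

    def tanh(self):
        out_data = np.tanh(self.data)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,))

        def bwd(g):
            self._accumulate(g * (1.0 - out_data * out_data))
        out._backward = bwd
        return out

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def gelu(x: Tensor) -> Tensor:
    """Exact Gaussian-error-linear unit, 0.5*x*(1+erf(x/sqrt(2)))."""
    xd = x.data
    cdf = 0.5 * (1.0 + erf(xd / np.sqrt(2.0)))
    out_data = xd * cdf
    if not (x.requires_grad and _GRAD_ENABLED):
        return Tensor(out_data)
    out = Tensor(out_data, True, (x,))
    pdf = np.exp(-0.5 * xd * xd) / np.sqrt(2.0 * np.pi)

    def bwd(g):
        x._accumulate(g * (cdf + xd * pdf))
    out._backward = bwd
    return out


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    xd = x.data
    m = xd.max(axis=axis, keepdims=True)
    z = xd - m
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out_data = z - lse
    if not (x.requires_grad and _GRAD_ENABLED):
        return Tensor(out_data)
    out = Tensor(out_data, True, (x,))
    sm = np.exp(out_data)

    def bwd(g):
        x._accumulate(g - sm * g.sum(axis=axis, keepdims=True))
    out._backward = bwd
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    xd = x.data
    m = xd.max(axis=axis, keepdims=True)
    e = np.exp(xd - m)
    out_data = e / e.sum(axis=axis, keepdims=True)
    if not (x.requires_grad and _GRAD_ENABLED):
        return Tensor(out_data)
    out = Tensor(out_data, True, (x,))

    def bwd(g):
        tmp = g * out_data
        x._accumulate(tmp - out_data * tmp.sum(axis=axis, keepdims=True))
    out._backward = bwd
    return out


def concatenate(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    if not (req and _GRAD_ENABLED):
        return Tensor(out_data)
    out = Tensor(out_data, True, tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])
    out._backward = bwd
    return out


def relative_attention_scores(q: Tensor, rel: Tensor, dist_idx: np.ndarray,
                              side: str) -> Tensor:
    """Position-bias term of relative key-query attention.

    q        : (B, H, L, dh) queries (side="q") or keys (side="k")
    rel      : (n_buckets, dh) learned relative-position embeddings
    dist_idx : (L, L) integer bucket index for each (query, key) offset
    returns  : (B, H, L, L) with entry [.., i, j] = q_i . rel[dist_idx[i, j]]
               (side="q") or k_j . rel[dist_idx[i, j]] (side="k")
    """
    if side not in ("q", "k"):
        raise ValueError("side must be 'q' or 'k'")
    rfull = rel.data[dist_idx]                      # (L, L, dh)
    sub = "bhid,ijd->bhij" if side == "q" else "bhjd,ijd->bhij"
    out_data = np.einsum(sub, q.data, rfull)
    req = q.requires_grad or rel.requires_grad
    if not (req and _GRAD_ENABLED):
        return Tensor(out_data)
    out = Tensor(out_data, True, (q, rel))

    def bwd(g):
        if q.requires_grad:
            back = "bhij,ijd->bhid" if side == "q" else "bhij,ijd->bhjd"
            q._accumulate(np.einsum(back, g, rfull))
        if rel.requires_grad:
            back = "bhij,bhid->ijd" if side == "q" else "bhij,bhjd->ijd"
            grfull = np.einsum(back, g, q.data)     # (L, L, dh)
            grel = np.zeros_like(rel.data)
            np.add.at(grel, dist_idx.ravel(), grfull.reshape(-1, grfull.shape[-1]))
            rel._accumulate(grel)
    out._backward = bwd
    return out
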