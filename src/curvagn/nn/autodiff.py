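"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps a float64 ndarray and records the operations
applied to it; calling :meth:`Tensor.backward` on a scalar result fills
``grad`` on every tensor created with ``requires_grad=True``.  Only the
operations the graph-attention network needs are implemented: arithmetic
with broadcasting, matmul, the nonlinearities, concatenation, row gather
and segment (scatter) sums, and reductions.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: Tuple[int, ...]) -> Array:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: Sequence["Tensor"] = (),
        _backward: Optional[Callable[[Array], None]] = None,
    ) -> None:
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[Array] = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = tuple(p for p in _parents if p.requires_grad)
        self._backward = _backward

    # -- graph plumbing ---------------------------------------------------
    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, grad: Array, owned: bool = True) -> None:
        # ``owned`` promises the caller will not hand the same array object
        # to another tensor; pass False for shared pass-through gradients.
        if self.grad is None:
            self.grad = grad if owned else grad.copy()
        elif self.grad.flags.writeable:
            self.grad += grad
        else:
            self.grad = self.grad + grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: List[Tensor] = []
        seen = set()

        def visit(t: Tensor) -> None:
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)

        def bw(g: Array) -> None:
            if self.requires_grad:
                gg = _unbroadcast(g, self.data.shape)
                self._accumulate(gg, owned=gg is not g)
            if other.requires_grad:
                gg = _unbroadcast(g, other.data.shape)
                other._accumulate(gg, owned=gg is not g)

        return Tensor(self.data + other.data, _parents=(self, other), _backward=bw)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bw(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor(-self.data, _parents=(self,), _backward=bw)

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)

        def bw(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(self.data * other.data, _parents=(self, other), _backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)

        def bw(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor(self.data / other.data, _parents=(self, other), _backward=bw)

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)

        def bw(g: Array) -> None:
            a, b = self.data, other.data
            if self.requires_grad:
                if b.ndim == 2:
                    self._accumulate(g @ b.T)
                elif a.ndim == 2:  # (n,d) @ (d,) -> (n,)
                    self._accumulate(np.outer(g, b))
                else:  # (d,) @ (d,) -> scalar
                    self._accumulate(g * b)
            if other.requires_grad:
                if a.ndim == 2:
                    other._accumulate(a.T @ g)
                elif b.ndim == 2:  # (d,) @ (d,m) -> (m,)
                    other._accumulate(np.outer(a, g))
                else:
                    other._accumulate(g * a)

        return Tensor(self.data @ other.data, _parents=(self, other), _backward=bw)

    # -- nonlinearities ---------------------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bw(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor(self.data * mask, _parents=(self,), _backward=bw)

    def leaky_relu(self, slope: float = 0.01) -> "Tensor":
        mask = self.data > 0
        factor = np.where(mask, 1.0, slope)

        def bw(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g * factor)

        return Tensor(self.data * factor, _parents=(self,), _backward=bw)

    def tanh(self) -> "Tensor":
        out = np.tanh(self.data)

        def bw(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g * (1.0 - out**2))

        return Tensor(out, _parents=(self,), _backward=bw)

    def exp(self) -> "Tensor":
        out = np.exp(self.data)

        def bw(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g * out)

        return Tensor(out, _parents=(self,), _backward=bw)

    def abs(self) -> "Tensor":
        sign = np.sign(self.data)

        def bw(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g * sign)

        return Tensor(np.abs(self.data), _parents=(self,), _backward=bw)

    def sqrt(self) -> "Tensor":
        out = np.sqrt(self.data)

        def bw(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g * 0.5 / out)

        return Tensor(out, _parents=(self,), _backward=bw)

    # -- shape ops --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def bw(g: Array) -> None:
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor(
            self.data.sum(axis=axis, keepdims=keepdims),
            _parents=(self,),
            _backward=bw,
        )

    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape

        def bw(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        return Tensor(self.data.reshape(*shape), _parents=(self,), _backward=bw)

    def cols(self, start: int, stop: int) -> "Tensor":
        """Column slice ``self[:, start:stop]`` of a 2-D tensor."""

        def bw(g: Array) -> None:
            if self.requires_grad:
                acc = np.zeros_like(self.data)
                acc[:, start:stop] = g
                self._accumulate(acc)

        return Tensor(self.data[:, start:stop], _parents=(self,), _backward=bw)

    def gather_rows(self, idx: Array, plan: "ScatterPlan" = None) -> "Tensor":
        """Row selection ``out[k] = self[idx[k]]`` (differentiable).

        ``plan`` (a :class:`ScatterPlan` over ``idx`` with ``n`` = number of
        rows of ``self``) speeds up the backward scatter-add when the same
        index array is reused across passes.
        """
        idx = np.asarray(idx, dtype=int)

        def bw(g: Array) -> None:
            if not self.requires_grad:
                return
            if plan is not None:
                self._accumulate(plan.scatter(g))
            else:
                acc = np.zeros_like(self.data)
                np.add.at(acc, idx, g)
                self._accumulate(acc)

        return Tensor(self.data[idx], _parents=(self,), _backward=bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g: Array) -> None:
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        _parents=tuple(tensors),
        _backward=bw,
    )


class ScatterPlan:
    """Precomputed sort order for repeated scatter-adds with one index array.

    Sorting the rows once and summing runs with ``np.add.reduceat`` is much
    faster than ``np.add.at`` when the same segmentation is applied every
    forward/backward pass (as it is for a graph's fixed edge/arc indices).
    """

    __slots__ = ("idx", "n", "order", "starts", "uniq")

    def __init__(self, idx: Array, n: int) -> None:
        self.idx = np.asarray(idx, dtype=int)
        self.n = int(n)
        self.order = np.argsort(self.idx, kind="stable")
        s = self.idx[self.order]
        if s.size:
            self.starts = np.flatnonzero(np.r_[True, s[1:] != s[:-1]])
            self.uniq = s[self.starts]
        else:
            self.starts = np.zeros(0, dtype=int)
            self.uniq = np.zeros(0, dtype=int)

    def scatter(self, rows: Array) -> Array:
        out = np.zeros((self.n,) + rows.shape[1:], dtype=np.float64)
        if self.idx.size:
            out[self.uniq] = np.add.reduceat(rows[self.order], self.starts, axis=0)
        return out


def segment_sum(
    t: Tensor, idx: Array, n_segments: int, plan: ScatterPlan = None
) -> Tensor:
    """Scatter-add rows of ``t`` into ``n_segments`` buckets by ``idx``."""
    idx = np.asarray(idx, dtype=int)
    if plan is not None:
        out = plan.scatter(t.data)
    else:
        out = np.zeros((n_segments,) + t.data.shape[1:], dtype=np.float64)
        np.add.at(out, idx, t.data)

    def bw(g: Array) -> None:
        if t.requires_grad:
            t._accumulate(g[idx])

    return Tensor(out, _parents=(t,), _backward=bw)


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax built from primitive ops."""
    shifted = t - Tensor(t.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)
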