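"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the network needs: broadcast arithmetic,
matrix products, pointwise nonlinearities, reductions, concatenation,
dropout, and two graph primitives — ``gather`` (select rows along axis 1)
and ``segment_sum`` (sum rows along axis 1 into groups) — whose index
bookkeeping is precomputed once per graph in a :class:`SegmentPlan`.

Gradients flow through a tape of closures released by ``backward`` on the
loss tensor; every op's adjoint is exact, and the test-suite checks them
against central finite differences.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np

__all__ = ["Tensor", "SegmentPlan", "Adam", "concat", "gather", "segment_sum"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient over the axes that broadcasting expanded."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward: Optional[Callable[[np.ndarray], None]] = None
        self._parents: tuple["Tensor", ...] = ()

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy() if isinstance(grad, np.ndarray) else np.asarray(grad)
        else:
            self.grad += grad

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    if id(p) not in seen:
                        stack.append((p, False))

        visit(self)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic -------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    def __add__(self, other):
        other = self._lift(other)
        a, b = self, other

        def back(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.data.shape))

        return self._make(a.data + b.data, (a, b), back)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def back(g):
            a._accumulate(-g)

        return self._make(-a.data, (a,), back)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        a, b = self, other

        def back(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return self._make(a.data * b.data, (a, b), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        a, b = self, other

        def back(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data**2), b.data.shape))

        return self._make(a.data / b.data, (a, b), back)

    def __pow__(self, exponent: float):
        a = self
        e = float(exponent)

        def back(g):
            a._accumulate(g * e * a.data ** (e - 1.0))

        return self._make(a.data**e, (a,), back)

    def matmul(self, other: "Tensor") -> "Tensor":
        """a @ b where a is (..., M, K) and b is 2-D (K, N)."""
        a, b = self, self._lift(other)
        out_data = a.data @ b.data

        def back(g):
            if a.requires_grad:
                a._accumulate(g @ b.data.T)
            if b.requires_grad:
                ga = a.data.reshape(-1, a.data.shape[-1]).T @ g.reshape(-1, g.shape[-1])
                b._accumulate(ga.astype(b.data.dtype))

        return self._make(out_data, (a, b), back)

    __matmul__ = matmul

    # -- pointwise --------------------------------------------------------
    def tanh(self):
        a = self
        y = np.tanh(a.data)

        def back(g):
            a._accumulate(g * (1.0 - y**2))

        return self._make(y, (a,), back)

    def sigmoid(self):
        a = self
        y = np.where(a.data >= 0, 1.0 / (1.0 + np.exp(-np.abs(a.data))),
                     np.exp(-np.abs(a.data)) / (1.0 + np.exp(-np.abs(a.data))))
        y = y.astype(a.data.dtype)

        def back(g):
            a._accumulate(g * y * (1.0 - y))

        return self._make(y, (a,), back)

    def exp(self):
        a = self
        y = np.exp(a.data)

        def back(g):
            a._accumulate(g * y)

        return self._make(y, (a,), back)

    def log(self):
        a = self

        def back(g):
            a._accumulate(g / a.data)

        return self._make(np.log(a.data), (a,), back)

    def relu(self):
        a = self
        mask = a.data > 0

        def back(g):
            a._accumulate(g * mask)

        return self._make(a.data * mask, (a,), back)

    def leaky_relu(self, slope: float = 0.2):
        a = self
        mask = a.data > 0
        scale = np.where(mask, 1.0, slope).astype(a.data.dtype)

        def back(g):
            a._accumulate(g * scale)

        return self._make(a.data * scale, (a,), back)

    def elu(self, alpha: float = 1.0):
        a = self
        neg = np.minimum(a.data, 0.0)
        expm = alpha * np.expm1(neg)
        y = np.where(a.data > 0, a.data, expm).astype(a.data.dtype)
        dydx = np.where(a.data > 0, 1.0, expm + alpha).astype(a.data.dtype)

        def back(g):
            a._accumulate(g * dydx)

        return self._make(y, (a,), back)

    def softplus(self):
        """Numerically stable log(1 + exp(x)); gradient is sigmoid(x)."""
        a = self
        y = np.maximum(a.data, 0.0) + np.log1p(np.exp(-np.abs(a.data)))
        sig = 1.0 / (1.0 + np.exp(-np.abs(a.data)))
        sig = np.where(a.data >= 0, sig, 1.0 - sig).astype(a.data.dtype)

        def back(g):
            a._accumulate(g * sig)

        return self._make(y.astype(a.data.dtype), (a,), back)

    # -- reductions / shaping --------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        y = a.data.sum(axis=axis, keepdims=keepdims)

        def back(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.data.shape).astype(a.data.dtype))

        return self._make(y, (a,), back)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        a = self
        orig = a.data.shape

        def back(g):
            a._accumulate(g.reshape(orig))

        return self._make(a.data.reshape(*shape), (a,), back)

    def dropout(self, rate: float, rng: np.random.Generator, train: bool):
        if not train or rate <= 0.0:
            return self
        a = self
        keep = 1.0 - rate
        mask = (rng.random(a.data.shape) < keep).astype(a.data.dtype) / keep

        def back(g):
            a._accumulate(g * mask)

        return self._make(a.data * mask, (a,), back)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis))
    parents = tuple(t for t in tensors if t.requires_grad)
    if parents:
        sizes = [d.shape[axis] for d in datas]
        splits = np.cumsum(sizes)[:-1]

        def back(g):
            pieces = np.split(g, splits, axis=axis)
            for t, piece in zip(tensors, pieces):
                if t.requires_grad:
                    t._accumulate(piece)

        out.requires_grad = True
        out._parents = parents
        out._backward = back
    return out


class SegmentPlan:
    """Precomputed bookkeeping for gather/segment ops over one index vector.

    ``idx`` maps each of E slots to one of ``n_targets`` groups.  Segment
    sums run over slots sorted by group via ``np.add.reduceat``; the same
    sorted layout serves as the scatter plan for gather's adjoint.
    """

    def __init__(self, idx: np.ndarray, n_targets: int):
        idx = np.asarray(idx, dtype=np.int64)
        if idx.size and (idx.min() < 0 or idx.max() >= n_targets):
            raise ValueError("index out of range")
        self.idx = idx
        self.n_targets = int(n_targets)
        self.perm = np.argsort(idx, kind="stable")
        sorted_idx = idx[self.perm]
        if idx.size:
            change = np.flatnonzero(np.diff(sorted_idx)) + 1
            self.starts = np.concatenate([[0], change])
            self.group_ids = sorted_idx[self.starts]
        else:
            self.starts = np.zeros(0, dtype=np.int64)
            self.group_ids = np.zeros(0, dtype=np.int64)
        self.covers_all = self.group_ids.size == n_targets

    def segment_reduce(self, values: np.ndarray, op=np.add) -> np.ndarray:
        """Reduce values (B, E, ...) along axis 1 by group -> (B, n_targets, ...).

        Raw numpy; slots must sit on axis 1 (add a trailing singleton axis for
        per-slot scalars).
        """
        v = values[:, self.perm]
        red = op.reduceat(v, self.starts, axis=1)
        if self.covers_all:
            return red
        shape = list(values.shape)
        shape[1] = self.n_targets
        out = np.zeros(shape, dtype=values.dtype)
        out[:, self.group_ids] = red
        return out

    def counts(self) -> np.ndarray:
        return np.bincount(self.idx, minlength=self.n_targets)


def gather(t: Tensor, plan: SegmentPlan) -> Tensor:
    """Select rows along axis 1: (B, N, D) -> (B, E, D) at plan.idx."""
    a = t
    idx = plan.idx
    out_data = a.data[:, idx]

    def back(g):
        gs = g[:, plan.perm]
        red = np.add.reduceat(gs, plan.starts, axis=1) if idx.size else gs[:, :0]
        full = np.zeros_like(a.data)
        full[:, plan.group_ids] = red
        a._accumulate(full)

    out = Tensor(out_data)
    if a.requires_grad:
        out.requires_grad = True
        out._parents = (a,)
        out._backward = back
    return out


def segment_sum(t: Tensor, plan: SegmentPlan) -> Tensor:
    """Sum rows along axis 1 into groups: (B, E, D) -> (B, n_targets, D)."""
    a = t
    out_data = plan.segment_reduce(a.data)

    def back(g):
        a._accumulate(g[:, plan.idx])

    out = Tensor(out_data)
    if a.requires_grad:
        out.requires_grad = True
        out._parents = (a,)
        out._backward = back
    return out


class Adam:
    """Adam with decoupled-from-loss L2 (weight decay added to the gradient)."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            if self.weight_decay and not k.endswith("_bias"):
                g = g + self.weight_decay * p.data
            m = self._m[k] = self.b1 * self._m[k] + (1 - self.b1) * g
            v = self._v[k] = self.b2 * self._v[k] + (1 - self.b2) * g**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data = (p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
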