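"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the attention network needs: broadcasting
arithmetic, (batched) matrix products, the activation functions, masked and
plain softmax, row gathering and dropout.  Everything is float64; graphs are
built eagerly and freed after ``backward``.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "stack",
    "leaky_relu",
    "elu",
    "tanh",
    "softmax",
    "masked_softmax",
    "log_softmax",
    "dropout",
    "take_rows",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data)
        if data.dtype != np.float32:  # float32 opts in, everything else is f64
            data = data.astype(np.float64, copy=False)
        self.data = data
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _node(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy() if g.base is not None else g
        else:
            self.grad = self.grad + g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        while stack_:  # iterative DFS; graphs can be a few thousand nodes deep
            node = stack_[-1]
            if id(node) in seen:
                stack_.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen]
            if unvisited:
                stack_.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(stack_.pop())
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                node._parents = ()
                node._backward = None

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        a, b = self, self._lift(other)

        def back(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        return self._node(a.data + b.data, (a, b), back)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return self._node(-a.data, (a,), lambda g: a._accumulate(-g) if a.requires_grad else None)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        a, b = self, self._lift(other)

        def back(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return self._node(a.data * b.data, (a, b), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, self._lift(other)

        def back(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data**2), b.shape))

        return self._node(a.data / b.data, (a, b), back)

    def __matmul__(self, other):
        a, b = self, self._lift(other)

        def back(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accumulate(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accumulate(_unbroadcast(gb, b.shape))

        return self._node(a.data @ b.data, (a, b), back)

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        a = self
        old = a.shape
        return self._node(
            a.data.reshape(*shape),
            (a,),
            lambda g: a._accumulate(g.reshape(old)) if a.requires_grad else None,
        )

    def transpose(self, *axes):
        a = self
        inv = tuple(np.argsort(axes))
        return self._node(
            a.data.transpose(*axes),
            (a,),
            lambda g: a._accumulate(g.transpose(*inv)) if a.requires_grad else None,
        )

    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def back(g):
            if not a.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.shape).astype(a.data.dtype))

        return self._node(a.data.sum(axis=axis, keepdims=keepdims), (a,), back)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else axis
            n = int(np.prod([self.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    parents = tuple(tensors)

    def back(g):
        for i, t in enumerate(parents):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=axis))

    return Tensor._node(np.stack([t.data for t in parents], axis=axis), parents, back)


def tanh(x: Tensor) -> Tensor:
    y = np.tanh(x.data)
    return Tensor._node(
        y, (x,), lambda g: x._accumulate(g * (1.0 - y**2)) if x.requires_grad else None
    )


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    pos = x.data > 0
    y = np.where(pos, x.data, slope * x.data)
    return Tensor._node(
        y,
        (x,),
        lambda g: x._accumulate(g * np.where(pos, 1.0, slope)) if x.requires_grad else None,
    )


def elu(x: Tensor, alpha: float = 1.0) -> Tensor:
    neg = x.data <= 0
    expm1 = alpha * np.expm1(np.minimum(x.data, 0.0))
    y = np.where(neg, expm1, x.data)

    def back(g):
        if x.requires_grad:
            x._accumulate(g * np.where(neg, expm1 + alpha, 1.0))

    return Tensor._node(y, (x,), back)


def _softmax_backward(x: Tensor, p: np.ndarray, axis: int):
    def back(g):
        if x.requires_grad:
            x._accumulate(p * (g - (g * p).sum(axis=axis, keepdims=True)))

    return back


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=axis, keepdims=True)
    return Tensor._node(p, (x,), _softmax_backward(x, p, axis))


def masked_softmax(
    x: Tensor, mask: np.ndarray, axis: int = -1, additive_mask: np.ndarray | None = None
) -> Tensor:
    """Softmax over the entries where ``mask`` is True; masked entries get 0.

    Rows with no admissible entry yield all-zero probability rows.  A
    precomputed ``additive_mask`` (0 where admissible, -inf elsewhere, same
    trailing shape as ``mask``) avoids rebuilding it per call.
    """
    if additive_mask is None:
        additive_mask = np.where(np.broadcast_to(mask, x.shape), 0.0, -np.inf)
    neg = x.data + additive_mask
    m = neg.max(axis=axis, keepdims=True)
    m[~np.isfinite(m)] = 0.0
    e = np.exp(neg - m)  # exp(-inf) = 0 handles the masked entries
    denom = e.sum(axis=axis, keepdims=True)
    denom[denom == 0.0] = 1.0
    p = e
    p /= denom
    return Tensor._node(p, (x,), _softmax_backward(x, p, axis))


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    y = z - lse
    p = np.exp(y)

    def back(g):
        if x.requires_grad:
            x._accumulate(g - p * g.sum(axis=axis, keepdims=True))

    return Tensor._node(y, (x,), back)


def dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; caller decides whether it is training time."""
    if rate <= 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.shape, dtype=np.float32) < keep).astype(x.data.dtype)
    mask /= x.data.dtype.type(keep)
    return Tensor._node(
        x.data * mask, (x,), lambda g: x._accumulate(g * mask) if x.requires_grad else None
    )


def take_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx)

    def back(g):
        if x.requires_grad:
            acc = np.zeros_like(x.data)
            np.add.at(acc, idx, g)
            x._accumulate(acc)

    return Tensor._node(x.data[idx], (x,), back)


class Adam:
    """Adam with optional coupled L2 weight decay on selected parameters."""

    def __init__(
        self,
        params: Iterable[tuple[Tensor, bool]],
        lr: float = 0.005,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = [(t, decay) for t, decay in params]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(t.data) for t, _ in self.params]
        self._v = [np.zeros_like(t.data) for t, _ in self.params]

    def zero_grad(self) -> None:
        for t, _ in self.params:
            t.grad = None

    def step(self) -> None:
        self.t += 1
        for i, (t, decay) in enumerate(self.params):
            if t.grad is None:
                continue
            g = t.grad
            if decay and self.weight_decay:
                g = g + self.weight_decay * t.data
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g**2
            mhat = self._m[i] / (1 - self.b1**self.t)
            vhat = self._v[i] / (1 - self.b2**self.t)
            t.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
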