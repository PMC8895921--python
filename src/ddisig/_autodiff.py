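"""Minimal reverse-mode automatic differentiation over numpy arrays.

The two models in this package (the expression generator and the gated
translating-embedding scorer) are small dense networks trained with
first-order methods.  This module provides the only machinery they need:
a :class:`Tensor` wrapping a float64 ndarray, a closed set of differentiable
ops (matmul, elementwise arithmetic, sigmoid/relu/tanh, row gather with
scatter-add backward, batched matrix-vector products for per-relation
projection matrices, row-wise L2 norms, reductions), and an Adam optimizer.

Gradients are accumulated by topological-order backpropagation.  All math is
float64; forward passes are bit-reproducible for fixed inputs and parameters.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "param",
    "constant",
    "matmul",
    "gather",
    "bmv",
    "bmv_t",
    "sigmoid",
    "relu",
    "tanh",
    "l2norm_rows",
    "concat",
    "mean",
    "total",
    "powc",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """Node in the autodiff graph.

    ``requires_grad`` marks trainable parameters (and anything downstream of
    one).  ``backward()`` may only be called on a scalar-valued tensor.
    """

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

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ---- graph construction helpers -------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _accum(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # ---- arithmetic ------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        out = Tensor(
            self.data + other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            parents=(self, other),
        )

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, requires_grad=self.requires_grad, parents=(self,))

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(-g)

        out._backward = bwd
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        out = Tensor(
            self.data * other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            parents=(self, other),
        )

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __matmul__(self, other) -> "Tensor":
        return matmul(self, Tensor._lift(other))

    # ---- backward driver -------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def param(data, rng: np.random.Generator | None = None, scale: float | None = None) -> Tensor:
    """Create a trainable parameter.

    With ``rng``, ``data`` is a shape tuple and the parameter is drawn
    N(0, scale^2); ``scale`` defaults to Glorot (sqrt(2 / (fan_in + fan_out))).
    """
    if rng is not None:
        shape = tuple(data)
        if scale is None:
            fan_in = shape[-1] if len(shape) > 1 else shape[0]
            fan_out = shape[-2] if len(shape) > 1 else shape[0]
            scale = float(np.sqrt(2.0 / (fan_in + fan_out)))
        data = rng.normal(0.0, scale, size=shape)
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


def constant(data) -> Tensor:
    return Tensor(data, requires_grad=False)


# ---- linear algebra ------------------------------------------------------


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(
        a.data @ b.data,
        requires_grad=a.requires_grad or b.requires_grad,
        parents=(a, b),
    )

    def bwd(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accum(g @ b.data.T)
        if b.requires_grad:
            b._accum(a.data.T @ g)

    out._backward = bwd
    return out


def gather(table: Tensor, idx: np.ndarray) -> Tensor:
    """Row lookup ``table[idx]`` with scatter-add backward.

    ``table`` has shape (R, ...) and ``idx`` is an int array of shape (B,);
    the result has shape (B, ...).  Used both for per-drug hidden states and
    for per-side-effect relation parameters.
    """
    idx = np.asarray(idx, dtype=np.intp)
    out = Tensor(table.data[idx], requires_grad=table.requires_grad, parents=(table,))

    def bwd(g: np.ndarray) -> None:
        if table.requires_grad:
            acc = np.zeros_like(table.data)
            np.add.at(acc, idx, g)
            table._accum(acc)

    out._backward = bwd
    return out


def bmv(m: Tensor, v: Tensor) -> Tensor:
    """Batched matrix-vector product: (B,E,D) x (B,D) -> (B,E)."""
    out = Tensor(
        np.einsum("bed,bd->be", m.data, v.data),
        requires_grad=m.requires_grad or v.requires_grad,
        parents=(m, v),
    )

    def bwd(g: np.ndarray) -> None:
        if m.requires_grad:
            m._accum(np.einsum("be,bd->bed", g, v.data))
        if v.requires_grad:
            v._accum(np.einsum("be,bed->bd", g, m.data))

    out._backward = bwd
    return out


def bmv_t(m: Tensor, v: Tensor) -> Tensor:
    """Batched transposed product: (B,E,D) x (B,E) -> (B,D)."""
    out = Tensor(
        np.einsum("bed,be->bd", m.data, v.data),
        requires_grad=m.requires_grad or v.requires_grad,
        parents=(m, v),
    )

    def bwd(g: np.ndarray) -> None:
        if m.requires_grad:
            m._accum(np.einsum("bd,be->bed", g, v.data))
        if v.requires_grad:
            v._accum(np.einsum("bd,bed->be", g, m.data))

    out._backward = bwd
    return out


# ---- nonlinearities ------------------------------------------------------


def sigmoid(x: Tensor) -> Tensor:
    with np.errstate(over="ignore"):
        s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, requires_grad=x.requires_grad, parents=(x,))

    def bwd(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accum(g * s * (1.0 - s))

    out._backward = bwd
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(np.where(mask, x.data, 0.0), requires_grad=x.requires_grad, parents=(x,))

    def bwd(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accum(g * mask)

    out._backward = bwd
    return out


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)
    out = Tensor(t, requires_grad=x.requires_grad, parents=(x,))

    def bwd(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accum(g * (1.0 - t * t))

    out._backward = bwd
    return out


def powc(x: Tensor, p: float) -> Tensor:
    """Elementwise power with a constant exponent."""
    out = Tensor(np.power(x.data, p), requires_grad=x.requires_grad, parents=(x,))

    def bwd(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accum(g * p * np.power(x.data, p - 1.0))

    out._backward = bwd
    return out


def l2norm_rows(x: Tensor) -> Tensor:
    """Row-wise Euclidean norm: (B, D) -> (B,).  Zero rows get zero gradient."""
    n = np.sqrt(np.sum(x.data * x.data, axis=1))
    out = Tensor(n, requires_grad=x.requires_grad, parents=(x,))

    def bwd(g: np.ndarray) -> None:
        if x.requires_grad:
            safe = np.where(n > 0, n, 1.0)
            x._accum((g / safe)[:, None] * x.data)

    out._backward = bwd
    return out


def concat(parts: Sequence[Tensor], axis: int = 1) -> Tensor:
    datas = [p.data for p in parts]
    out = Tensor(
        np.concatenate(datas, axis=axis),
        requires_grad=any(p.requires_grad for p in parts),
        parents=tuple(parts),
    )
    splits = np.cumsum([d.shape[axis] for d in datas])[:-1]

    def bwd(g: np.ndarray) -> None:
        for piece, p in zip(np.split(g, splits, axis=axis), parts):
            if p.requires_grad:
                p._accum(piece)

    out._backward = bwd
    return out


def mean(x: Tensor, axis: int | None = None, keepdims: bool = False) -> Tensor:
    out = Tensor(
        np.mean(x.data, axis=axis, keepdims=keepdims),
        requires_grad=x.requires_grad,
        parents=(x,),
    )
    if axis is None:
        count = x.data.size
    else:
        count = x.data.shape[axis]

    def bwd(g: np.ndarray) -> None:
        if x.requires_grad:
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            x._accum(np.broadcast_to(g / count, x.data.shape))

    out._backward = bwd
    return out


def total(x: Tensor) -> Tensor:
    """Sum of all elements."""
    out = Tensor(np.sum(x.data), requires_grad=x.requires_grad, parents=(x,))

    def bwd(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accum(np.broadcast_to(g, x.data.shape))

    out._backward = bwd
    return out


class Adam:
    """Adam with optional decoupled weight decay.

    Weight decay is applied multiplicatively (AdamW-style) so that a zero
    learning rate leaves parameters bit-identical.
    """

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            update = (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            if self.weight_decay:
                update = update + self.weight_decay * p.data
            p.data -= lr * update
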