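"""Minimal reverse-mode automatic differentiation on numpy arrays.

The model is a fixed, modest-size computation graph (a few dozen dense
operations per forward pass), so a compact tape-based engine is all the
training loop needs.  Every op records a closure that maps the output
gradient back to its parents; ``backward`` walks the tape in reverse
topological order.  Broadcasting in ``+ - * /`` is supported and undone in
the backward pass by summing over the broadcast axes.

Gradient correctness is pinned by central finite-difference checks in the
test suite.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "matmul", "relu", "sigmoid", "log", "sqrt", "AdamW"]


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        value,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.value = np.asarray(value, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    @property
    def shape(self):
        return self.value.shape

    # ---- graph walk -----------------------------------------------------

    def backward(self, seed: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep at high epoch counts
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
        self.grad = np.ones_like(self.value) if seed is None else np.asarray(seed, float)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.array(g, dtype=float, copy=True)
        else:
            self.grad += g

    # ---- arithmetic -----------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        out_val = self.value + other.value

        def bw(g, a=self, b=other, shapes=(self.shape, other.shape)):
            a._accumulate(_unbroadcast(g, shapes[0]))
            b._accumulate(_unbroadcast(g, shapes[1]))

        return Tensor(out_val, _parents=(self, other), _backward=lambda g: bw(g))

    __radd__ = __add__

    def __neg__(self):
        return Tensor(
            -self.value,
            _parents=(self,),
            _backward=lambda g, a=self: a._accumulate(-g),
        )

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out_val = self.value * other.value

        def bw(g, a=self, b=other):
            a._accumulate(_unbroadcast(g * b.value, a.shape))
            b._accumulate(_unbroadcast(g * a.value, b.shape))

        return Tensor(out_val, _parents=(self, other), _backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out_val = self.value / other.value

        def bw(g, a=self, b=other):
            a._accumulate(_unbroadcast(g / b.value, a.shape))
            b._accumulate(_unbroadcast(-g * a.value / b.value**2, b.shape))

        return Tensor(out_val, _parents=(self, other), _backward=bw)

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    # ---- shape ops ------------------------------------------------------

    @property
    def T(self):
        return Tensor(
            self.value.T,
            _parents=(self,),
            _backward=lambda g, a=self: a._accumulate(g.T),
        )

    def sum(self, axis=None, keepdims: bool = False):
        out_val = self.value.sum(axis=axis, keepdims=keepdims)

        def bw(g, a=self):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accumulate(np.broadcast_to(gg, a.shape).copy())

        return Tensor(out_val, _parents=(self,), _backward=bw)

    def mean(self, axis=None, keepdims: bool = False):
        count = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def rows(self, start: int, stop: int):
        """Row slice [start:stop) as a view into the graph."""

        def bw(g, a=self):
            full = np.zeros_like(a.value)
            full[start:stop] = g
            a._accumulate(full)

        return Tensor(self.value[start:stop], _parents=(self,), _backward=bw)

    def take_flat(self, flat_indices: np.ndarray):
        """Gather entries by flat index into a 1-D tensor."""
        idx = np.asarray(flat_indices, dtype=np.intp)
        out_val = self.value.ravel()[idx]

        def bw(g, a=self):
            full = np.zeros(a.value.size)
            np.add.at(full, idx, g)
            a._accumulate(full.reshape(a.shape))

        return Tensor(out_val, _parents=(self,), _backward=bw)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    g = grad
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_val = a.value @ b.value

    def bw(g):
        a._accumulate(g @ b.value.T)
        b._accumulate(a.value.T @ g)

    return Tensor(out_val, _parents=(a, b), _backward=bw)


def relu(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    mask = a.value > 0
    return Tensor(
        np.where(mask, a.value, 0.0),
        _parents=(a,),
        _backward=lambda g: a._accumulate(g * mask),
    )


def sigmoid(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    out_val = 1.0 / (1.0 + np.exp(-a.value))
    return Tensor(
        out_val,
        _parents=(a,),
        _backward=lambda g: a._accumulate(g * out_val * (1.0 - out_val)),
    )


def log(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    return Tensor(
        np.log(a.value),
        _parents=(a,),
        _backward=lambda g: a._accumulate(g / a.value),
    )


def sqrt(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    out_val = np.sqrt(a.value)
    return Tensor(
        out_val,
        _parents=(a,),
        _backward=lambda g: a._accumulate(g / (2.0 * out_val)),
    )


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_val = np.concatenate([t.value for t in tensors], axis=axis)
    sizes = [t.value.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    return Tensor(out_val, _parents=tuple(tensors), _backward=bw)


class AdamW:
    """Adam with decoupled weight decay, matching the usual defaults."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]
        self._t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1 - b1**self._t)
            v_hat = v / (1 - b2**self._t)
            p.value -= self.lr * (
                m_hat / (np.sqrt(v_hat) + self.eps) + self.weight_decay * p.value
            )
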