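"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The network, the training losses, and the gradient-based backbone
idealization all differentiate through this engine.  It implements exactly
the operation set those components need: elementwise arithmetic,
reductions, indexing, concatenation, ``einsum`` contractions, and the
nonlinearities of the architecture (sigmoid, softplus, relu, sqrt, exp,
acos, atan2).  Everything is float64 and single-threaded-deterministic.

A :class:`Tensor` wraps an ``ndarray`` and records the backward closure of
the op that produced it; :meth:`Tensor.backward` runs a topological sweep
accumulating gradients into every reachable leaf with ``requires_grad``.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "tensor", "concat", "stack", "einsum", "where",
           "atan2", "softmax", "layer_norm"]


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        raise TypeError("expected raw array, got Tensor")
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward",
                 "_accumulate")
    __array_priority__ = 100  # numpy defers binary ops to us

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that requires no grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        while stack:  # iterative DFS; graphs can be deep (training steps)
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            pending = [p for p in node._parents
                       if p.requires_grad and id(p) not in seen]
            if pending:
                stack.extend(pending)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                node._accumulate = grads  # type: ignore[attr-defined]
                node._backward(g)
                del node._accumulate  # type: ignore[attr-defined]

    def _send(self, parent: "Tensor", g: np.ndarray) -> None:
        if not parent.requires_grad:
            return
        grads: dict[int, np.ndarray] = self._accumulate  # type: ignore[attr-defined]
        key = id(parent)
        if key in grads:
            grads[key] = grads[key] + g
        else:
            grads[key] = g

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            out._send(self, _unbroadcast(g, self.shape))
            out._send(other, _unbroadcast(g, other.shape))

        out = Tensor._make(out_data, (self, other), backward)
        return out

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            out._send(self, -g)

        out = Tensor._make(-self.data, (self,), backward)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            out._send(self, _unbroadcast(g * other.data, self.shape))
            out._send(other, _unbroadcast(g * self.data, other.shape))

        out = Tensor._make(out_data, (self, other), backward)
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            out._send(self, _unbroadcast(g / other.data, self.shape))
            out._send(other, _unbroadcast(-g * self.data / other.data ** 2,
                                          other.shape))

        out = Tensor._make(out_data, (self, other), backward)
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        p = float(p)
        out_data = self.data ** p

        def backward(g):
            out._send(self, g * p * self.data ** (p - 1.0))

        out = Tensor._make(out_data, (self,), backward)
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.data.ndim == 1 and other.data.ndim == 1:
                out._send(self, g * other.data)
                out._send(other, g * self.data)
                return
            a, b = self.data, other.data
            ga = g[..., None] * b if b.ndim == 1 else g @ np.swapaxes(b, -1, -2)
            if a.ndim == 1:
                gb = np.einsum("i,...j->...ij", a, g) if g.ndim else np.outer(a, g)
                gb = a[:, None] * g if g.ndim == 1 else gb
            else:
                gb = np.swapaxes(a, -1, -2) @ (g[..., None, :] if g.ndim == b.ndim - 1 else g)
            out._send(self, _unbroadcast(ga, self.shape))
            out._send(other, _unbroadcast(gb, other.shape))

        out = Tensor._make(out_data, (self, other), backward)
        return out

    # -- elementwise functions ------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            out._send(self, g * out_data)

        out = Tensor._make(out_data, (self,), backward)
        return out

    def log(self):
        def backward(g):
            out._send(self, g / self.data)

        out = Tensor._make(np.log(self.data), (self,), backward)
        return out

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            out._send(self, g / (2.0 * out_data))

        out = Tensor._make(out_data, (self,), backward)
        return out

    def sigmoid(self):
        z = np.clip(self.data, -500.0, 500.0)  # overflow guard, exact in range
        out_data = 1.0 / (1.0 + np.exp(-z))

        def backward(g):
            out._send(self, g * out_data * (1.0 - out_data))

        out = Tensor._make(out_data, (self,), backward)
        return out

    def softplus(self):
        out_data = np.logaddexp(0.0, self.data)

        def backward(g):
            z = np.clip(self.data, -500.0, 500.0)
            out._send(self, g / (1.0 + np.exp(-z)))

        out = Tensor._make(out_data, (self,), backward)
        return out

    def relu(self):
        mask = self.data > 0

        def backward(g):
            out._send(self, g * mask)

        out = Tensor._make(self.data * mask, (self,), backward)
        return out

    def abs(self):
        sign = np.sign(self.data)

        def backward(g):
            out._send(self, g * sign)

        out = Tensor._make(np.abs(self.data), (self,), backward)
        return out

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            out._send(self, g * (1.0 - out_data ** 2))

        out = Tensor._make(out_data, (self,), backward)
        return out

    def acos(self):
        def backward(g):
            out._send(self, -g / np.sqrt(1.0 - self.data ** 2))

        out = Tensor._make(np.arccos(self.data), (self,), backward)
        return out

    def cos(self):
        def backward(g):
            out._send(self, -g * np.sin(self.data))

        out = Tensor._make(np.cos(self.data), (self,), backward)
        return out

    def sin(self):
        def backward(g):
            out._send(self, g * np.cos(self.data))

        out = Tensor._make(np.sin(self.data), (self,), backward)
        return out

    def clamp(self, lo: float | None = None, hi: float | None = None):
        mask = np.ones_like(self.data, dtype=bool)
        if lo is not None:
            mask &= self.data >= lo
        if hi is not None:
            mask &= self.data <= hi

        def backward(g):
            out._send(self, g * mask)

        out = Tensor._make(np.clip(self.data, lo, hi), (self,), backward)
        return out

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            out._send(self, np.broadcast_to(g, self.shape).copy())

        out = Tensor._make(out_data, (self,), backward)
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old_shape = self.shape

        def backward(g):
            out._send(self, g.reshape(old_shape))

        out = Tensor._make(self.data.reshape(shape), (self,), backward)
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)

        def backward(g):
            out._send(self, g.transpose(inv))

        out = Tensor._make(self.data.transpose(axes), (self,), backward)
        return out

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            out._send(self, full)

        out = Tensor._make(out_data, (self,), backward)
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def tensor(x, requires_grad: bool = False) -> Tensor:
    return Tensor(np.asarray(x, dtype=np.float64), requires_grad=requires_grad)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            out._send(t, g[tuple(sl)])

    out = Tensor._make(out_data, ts, backward)
    return out


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in ts], axis=axis)

    def backward(g):
        for i, t in enumerate(ts):
            out._send(t, np.take(g, i, axis=axis))

    out = Tensor._make(out_data, ts, backward)
    return out


def einsum(subscripts: str, *operands: Tensor) -> Tensor:
    """Einstein summation with reverse-mode gradients.

    Every input index must appear either in the output or in another
    operand (contraction-style specs); this covers all uses in the package.
    """
    ops = [as_tensor(o) for o in operands]
    in_spec, out_spec = subscripts.replace(" ", "").split("->")
    in_subs = in_spec.split(",")
    out_data = np.einsum(subscripts, *[o.data for o in ops], optimize=True)

    def backward(g):
        for i, op in enumerate(ops):
            if not op.requires_grad:
                continue
            others = [s for j, s in enumerate(in_subs) if j != i]
            other_ops = [o.data for j, o in enumerate(ops) if j != i]
            spec = ",".join([out_spec] + others) + "->" + in_subs[i]
            gi = np.einsum(spec, g, *other_ops, optimize=True)
            out._send(op, gi)

    out = Tensor._make(out_data, ops, backward)
    return out


def where(cond, a, b) -> Tensor:
    """Select elementwise; `cond` is a constant boolean array."""
    cond = np.asarray(cond, dtype=bool)
    a, b = as_tensor(a), as_tensor(b)
    out_data = np.where(cond, a.data, b.data)

    def backward(g):
        out._send(a, _unbroadcast(np.where(cond, g, 0.0), a.shape))
        out._send(b, _unbroadcast(np.where(cond, 0.0, g), b.shape))

    out = Tensor._make(out_data, (a, b), backward)
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Fused stable softmax along `axis` with analytic backward."""
    x = as_tensor(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    ex = np.exp(shifted)
    y = ex / ex.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        out._send(x, y * (g - dot))

    out = Tensor._make(y, (x,), backward)
    return out


def layer_norm(x: Tensor, gain: Tensor, offset: Tensor,
               eps: float = 1e-5) -> Tensor:
    """Fused last-axis layer normalization with analytic backward."""
    x, gain, offset = as_tensor(x), as_tensor(gain), as_tensor(offset)
    mu = x.data.mean(axis=-1, keepdims=True)
    cent = x.data - mu
    var = (cent * cent).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = cent * inv
    y = xhat * gain.data + offset.data

    def backward(g):
        d = x.data.shape[-1]
        gx_hat = g * gain.data
        term = (gx_hat - gx_hat.mean(axis=-1, keepdims=True)
                - xhat * (gx_hat * xhat).mean(axis=-1, keepdims=True))
        out._send(x, inv * term)
        red = tuple(range(g.ndim - 1))
        out._send(gain, (g * xhat).sum(axis=red))
        out._send(offset, g.sum(axis=red))

    out = Tensor._make(y, (x, gain, offset), backward)
    return out


def atan2(y: Tensor, x: Tensor) -> Tensor:
    y, x = as_tensor(y), as_tensor(x)
    out_data = np.arctan2(y.data, x.data)
    denom = y.data ** 2 + x.data ** 2

    def backward(g):
        out._send(y, _unbroadcast(g * x.data / denom, y.shape))
        out._send(x, _unbroadcast(-g * y.data / denom, x.shape))

    out = Tensor._make(out_data, (y, x), backward)
    return out
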