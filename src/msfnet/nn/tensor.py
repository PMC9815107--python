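"""Reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps a float32 ndarray and records the operations applied
to it; :meth:`Tensor.backward` accumulates gradients through the recorded
graph in reverse topological order.  The op set is deliberately small — just
what a convolutional classifier with attention gating needs — and every op
supports numpy broadcasting (gradients are summed back onto the original
shape).

Gradients are retained on *every* node, not only leaves, because the
class-activation-map explainer needs d(logit)/d(intermediate activation).
Graphs here are small enough that this costs little.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence, Tuple, Union

import numpy as np

ArrayLike = Union[np.ndarray, float, int, Sequence]


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that numpy broadcasting introduced."""
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data: ArrayLike,
        requires_grad: bool = False,
        _parents: Tuple["Tensor", ...] = (),
        _backward: Optional[Callable[[np.ndarray], None]] = None,
    ):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # -- introspection -------------------------------------------------
    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def numpy(self) -> np.ndarray:
        return self.data

    # -- graph machinery ----------------------------------------------
    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Backpropagate from this node (defaults to d(self)/d(self) = 1)."""
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep nets overflow the recursion limit
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
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other: ArrayLike) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor(out_data, _parents=(self, other), _backward=bwd)

    __radd__ = __add__

    def __mul__(self, other: ArrayLike) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor(out_data, _parents=(self, other), _backward=bwd)

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other: ArrayLike) -> "Tensor":
        return self + (-(other if isinstance(other, Tensor) else Tensor(other)))

    def __rsub__(self, other: ArrayLike) -> "Tensor":
        return Tensor(other) + (-self)

    def __truediv__(self, other: ArrayLike) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other: ArrayLike) -> "Tensor":
        return Tensor(other) * self ** -1.0

    def __pow__(self, exponent: float) -> "Tensor":
        if isinstance(exponent, Tensor):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data ** exponent

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def __matmul__(self, other: "Tensor") -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data @ other.data

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return Tensor(out_data, _parents=(self, other), _backward=bwd)

    # -- elementwise nonlinearities ------------------------------------
    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * out_data)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def log(self) -> "Tensor":
        out_data = np.log(self.data)

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def sigmoid(self) -> "Tensor":
        # numerically stable logistic
        out_data = np.where(
            self.data >= 0,
            1.0 / (1.0 + np.exp(-np.abs(self.data))),
            np.exp(-np.abs(self.data)) / (1.0 + np.exp(-np.abs(self.data))),
        ).astype(np.float32)

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out_data = self.data * mask

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def swish(self) -> "Tensor":
        """x * sigmoid(x) — the activation used throughout the backbone."""
        return self * self.sigmoid()

    def clip(self, lo: Optional[float] = None, hi: Optional[float] = None) -> "Tensor":
        out_data = np.clip(self.data, lo, hi)
        inside = np.ones_like(self.data, dtype=bool)
        if lo is not None:
            inside &= self.data >= lo
        if hi is not None:
            inside &= self.data <= hi

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * inside)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g: np.ndarray) -> None:
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.max(axis=axis, keepdims=keepdims)

        def bwd(g: np.ndarray) -> None:
            if not self.requires_grad:
                return
            out_b = self.data.max(axis=axis, keepdims=True)
            mask = (self.data == out_b).astype(np.float32)
            mask /= mask.sum(axis=axis, keepdims=True)  # ties share the gradient
            if axis is None:
                gb = g
            elif not keepdims:
                gb = np.expand_dims(g, axis)
            else:
                gb = g
            self._accumulate(mask * gb)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    # -- shape ops -----------------------------------------------------
    def reshape(self, *shape: int) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def transpose(self, axes: Sequence[int]) -> "Tensor":
        axes = tuple(axes)
        out_data = self.data.transpose(axes)
        inv = tuple(np.argsort(axes))

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def gather(self, index: np.ndarray, axis: int = 1) -> "Tensor":
        """Pick one entry per row along ``axis`` (e.g. true-class probability)."""
        index = np.asarray(index)
        idx = np.expand_dims(index, axis)
        out_data = np.take_along_axis(self.data, idx, axis=axis).squeeze(axis)

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.put_along_axis(full, idx, np.expand_dims(g, axis), axis=axis)
                self._accumulate(full)

        return Tensor(out_data, _parents=(self,), _backward=bwd)


def cat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    """Concatenate tensors along ``axis`` (channel fusion in the network)."""
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor(out_data, _parents=tuple(tensors), _backward=bwd)


def softmax(logits: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax with the exact Jacobian-vector backward."""
    shifted = logits.data - logits.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    p = (e / e.sum(axis=axis, keepdims=True)).astype(np.float32)

    def bwd(g: np.ndarray) -> None:
        if logits.requires_grad:
            dot = (g * p).sum(axis=axis, keepdims=True)
            logits._accumulate(p * (g - dot))

    return Tensor(p, _parents=(logits,), _backward=bwd)
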