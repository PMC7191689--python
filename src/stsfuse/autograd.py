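"""A small reverse-mode automatic differentiation engine on numpy arrays.

Provides exactly the operations the pair encoders and the fusion model need:
broadcasting elementwise arithmetic, matmul, the usual activations, reductions,
reshapes/concatenation, an embedding gather, and a numerically stable masked
softmax.  Gradients are accumulated by topological traversal from the output.
"""

from __future__ import annotations

from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

Arrayish = Union["Tensor", np.ndarray, float, int]

__all__ = ["Adam", "Tensor", "concat", "parameter", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum *grad* down to *shape* (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data: Arrayish,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Optional[Callable[[np.ndarray], None]] = None,
    ) -> None:
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=float)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(p for p in parents if p.requires_grad)
        self._backward = backward

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Backpropagate from this tensor (defaults to d(self)/d(self) = 1)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: List[Tensor] = []
        seen = set()

        def visit(node: "Tensor") -> None:
            stack = [(node, False)]
            while stack:
                t, processed = stack.pop()
                if processed:
                    topo.append(t)
                    continue
                if id(t) in seen:
                    continue
                seen.add(id(t))
                stack.append((t, True))
                for p in t._parents:
                    stack.append((p, False))

        visit(self)
        self._accumulate(np.asarray(grad, dtype=float))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------
    @staticmethod
    def _wrap(x: Arrayish) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other: Arrayish) -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __mul__(self, other: Arrayish) -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other: Arrayish) -> "Tensor":
        return self + (-self._wrap(other))

    def __rsub__(self, other: Arrayish) -> "Tensor":
        return self._wrap(other) + (-self)

    def __truediv__(self, other: Arrayish) -> "Tensor":
        return self * self._wrap(other) ** -1.0

    def __rtruediv__(self, other: Arrayish) -> "Tensor":
        return self._wrap(other) * self ** -1.0

    def __pow__(self, exponent: float) -> "Tensor":
        out = Tensor(self.data ** exponent, parents=(self,))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        out._backward = backward
        return out

    def __matmul__(self, other: "Tensor") -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def backward(g: np.ndarray) -> None:
            # swapaxes handles both plain 2-D and stacked (batched) matmul
            if self.requires_grad:
                self._accumulate(
                    _unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape)
                )
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape)
                )

        out._backward = backward
        return out

    # -- activations ------------------------------------------------------
    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * (1.0 - y * y))

        out._backward = backward
        return out

    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60.0, 60.0)))
        out = Tensor(y, parents=(self,))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * y * (1.0 - y))

        out._backward = backward
        return out

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * mask)

        out._backward = backward
        return out

    def exp(self) -> "Tensor":
        y = np.exp(self.data)
        out = Tensor(y, parents=(self,))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * y)

        out._backward = backward
        return out

    # -- reductions & shape ----------------------------------------------
    def sum(self, axis: Optional[int] = None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def backward(g: np.ndarray) -> None:
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis: Optional[int] = None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape: int) -> "Tensor":
        out = Tensor(self.data.reshape(shape), parents=(self,))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))

        out._backward = backward
        return out

    def transpose(self, *axes: int) -> "Tensor":
        axes_ = axes or tuple(reversed(range(self.ndim)))
        out = Tensor(self.data.transpose(axes_), parents=(self,))
        inv = np.argsort(axes_)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        out._backward = backward
        return out

    def __getitem__(self, key) -> "Tensor":
        out = Tensor(self.data[key], parents=(self,))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accumulate(full)

        out._backward = backward
        return out

    def take_rows(self, indices: np.ndarray) -> "Tensor":
        """Gather rows (embedding lookup); scatter-add on the way back."""
        indices = np.asarray(indices)
        out = Tensor(self.data[indices], parents=(self,))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, indices, g)
                self._accumulate(full)

        out._backward = backward
        return out


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    """Concatenate along *axis* with gradient routing back to each input."""
    tensors = [Tensor._wrap(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis), parents=tensors
    )
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = backward
    return out


def softmax(x: Tensor, mask: Optional[np.ndarray] = None, axis: int = -1) -> Tensor:
    """Stable softmax; positions where *mask* is falsy get zero probability."""
    if mask is not None:
        x = x + np.where(mask, 0.0, -1e9)
    shift = np.max(x.data, axis=axis, keepdims=True)  # constant, no grad
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def parameter(rng: np.random.Generator, *shape: int, scale: Optional[float] = None) -> Tensor:
    """Gaussian-initialized trainable tensor (scale defaults to Glorot-ish)."""
    if scale is None:
        fan = shape[0] if len(shape) > 1 else max(shape[0], 1)
        scale = 1.0 / np.sqrt(fan)
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 1e-3,
        betas: Tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m: Dict[int, np.ndarray] = {}
        self._v: Dict[int, np.ndarray] = {}

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for p in self.params:
            if p.grad is None:
                continue
            m = self._m.setdefault(id(p), np.zeros_like(p.data))
            v = self._v.setdefault(id(p), np.zeros_like(p.data))
            m += (1 - self.b1) * (p.grad - m)
            v += (1 - self.b2) * (p.grad * p.grad - v)
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
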