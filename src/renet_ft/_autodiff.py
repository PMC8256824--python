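"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the gene-disease association network
needs: broadcast-aware arithmetic, (batched) matrix multiplication,
embedding lookup, elementwise nonlinearities, axis reductions with
max-pooling, slicing, concatenation and reshape.  Gradients are checked
against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "embedding", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


def _as_tensor(value) -> "Tensor":
    if isinstance(value, Tensor):
        return value
    return Tensor(np.asarray(value, dtype=np.float64), requires_grad=False)


class Tensor:
    """A numpy array plus the tape needed to backpropagate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_prev", "_backward")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._prev = _prev
        self._backward = None

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        self.grad = g if self.grad is None else self.grad + g

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def backward(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-_as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return _as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __pow__(self, exponent: float) -> "Tensor":
        out = Tensor(self.data ** exponent, _prev=(self,))
        out._backward = lambda g: self._accum(g * exponent * self.data ** (exponent - 1))
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(np.matmul(self.data, other.data), _prev=(self, other))

        def backward(g):
            a, b = self.data, other.data
            ga = np.matmul(g, np.swapaxes(b, -1, -2))
            gb = np.matmul(np.swapaxes(a, -1, -2), g)
            self._accum(_unbroadcast(ga, a.shape))
            other._accum(_unbroadcast(gb, b.shape))

        out._backward = backward
        return out

    __matmul__ = matmul

    # -- nonlinearities -----------------------------------------------------

    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, _prev=(self,))
        out._backward = lambda g: self._accum(g * y * (1.0 - y))
        return out

    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)
        out = Tensor(y, _prev=(self,))
        out._backward = lambda g: self._accum(g * (1.0 - y * y))
        return out

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(self.data * mask, _prev=(self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def backward(g):
            if axis is None:
                self._accum(np.full_like(self.data, g))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int) -> "Tensor":
        """Max along one axis (no keepdims); subgradient to the argmax."""
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis).squeeze(axis)
        out = Tensor(out_data, _prev=(self,))

        def backward(g):
            full = np.zeros_like(self.data)
            np.put_along_axis(full, np.expand_dims(idx, axis), np.expand_dims(g, axis), axis)
            self._accum(full)

        out._backward = backward
        return out

    # -- shape ops ----------------------------------------------------------

    def reshape(self, *shape: int) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), _prev=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def __getitem__(self, key) -> "Tensor":
        out = Tensor(self.data[key], _prev=(self,))

        def backward(g):
            full = np.zeros_like(self.data)
            full[key] = g
            self._accum(full)

        out._backward = backward
        return out

    # -- autodiff driver ----------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
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
            for p in node._prev:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def item(self) -> float:
        return float(self.data)


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accum(g[tuple(sl)])

    out._backward = backward
    return out


def embedding(weights: Tensor, indices: np.ndarray) -> Tensor:
    """Row lookup ``weights[indices]`` with scatter-add gradient."""
    out = Tensor(weights.data[indices], _prev=(weights,))

    def backward(g):
        full = np.zeros_like(weights.data)
        np.add.at(full, indices, g)
        weights._accum(full)

    out._backward = backward
    return out


class Adam:
    """Adaptive first-order optimizer with bias correction."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1 ** self.t)
            v_hat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
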