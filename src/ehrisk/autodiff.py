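"""Compact reverse-mode automatic differentiation on numpy arrays.

A tape-based engine sized for the needs of the dual-stream risk model:
broadcast-aware arithmetic, batched matmul, reshape/transpose, reductions,
stable softmax/softplus/sigmoid, embedding gather with scatter-add backward,
and an Adam optimizer.  Gradients flow only into tensors created with
``requires_grad=True`` (parameters); everything else is treated as data.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- graph ---------------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def backward(self, grad=None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- arithmetic ----------------------------------------------------------

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)

        def bwd(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))
        return Tensor(self.data + other.data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)
        return Tensor(-self.data, parents=(self,), backward=bwd)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)

        def bwd(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))
        return Tensor(self.data * other.data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)

        def bwd(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(_unbroadcast(-g * self.data / other.data ** 2, other.data.shape))
        return Tensor(self.data / other.data, parents=(self, other), backward=bwd)

    def __matmul__(self, other):
        other = self._coerce(other)

        def bwd(g):
            ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
            self._accum(_unbroadcast(ga, self.data.shape))
            other._accum(_unbroadcast(gb, other.data.shape))
        return Tensor(np.matmul(self.data, other.data), parents=(self, other), backward=bwd)

    def pow_const(self, exponent: float):
        def bwd(g):
            self._accum(g * exponent * self.data ** (exponent - 1))
        return Tensor(self.data ** exponent, parents=(self,), backward=bwd)

    # -- shape ---------------------------------------------------------------

    def reshape(self, *shape):
        old = self.data.shape

        def bwd(g):
            self._accum(g.reshape(old))
        return Tensor(self.data.reshape(*shape), parents=(self,), backward=bwd)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def bwd(g):
            self._accum(g.transpose(*inv))
        return Tensor(self.data.transpose(*axes), parents=(self,), backward=bwd)

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            gg = g if keepdims else np.expand_dims(g, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())
        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,), backward=bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ------------------------------------------------------

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            self._accum(g * mask)
        return Tensor(np.where(mask, self.data, 0.0), parents=(self,), backward=bwd)

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accum(g * out_data)
        return Tensor(out_data, parents=(self,), backward=bwd)

    def log(self):
        def bwd(g):
            self._accum(g / self.data)
        return Tensor(np.log(self.data), parents=(self,), backward=bwd)

    def sigmoid(self):
        out_data = 0.5 * (1.0 + np.tanh(0.5 * self.data))

        def bwd(g):
            self._accum(g * out_data * (1.0 - out_data))
        return Tensor(out_data, parents=(self,), backward=bwd)

    def softplus(self):
        # log(1 + e^x), computed stably
        out_data = np.maximum(self.data, 0.0) + np.log1p(np.exp(-np.abs(self.data)))
        sig = 0.5 * (1.0 + np.tanh(0.5 * self.data))

        def bwd(g):
            self._accum(g * sig)
        return Tensor(out_data, parents=(self,), backward=bwd)

    def softmax(self):
        """Softmax along the last axis."""
        z = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=-1, keepdims=True)

        def bwd(g):
            dot = (g * out_data).sum(axis=-1, keepdims=True)
            self._accum(out_data * (g - dot))
        return Tensor(out_data, parents=(self,), backward=bwd)

    # -- lookup --------------------------------------------------------------

    def take_rows(self, indices: np.ndarray):
        """Embedding gather: ``self[indices]`` with scatter-add backward."""
        indices = np.asarray(indices)

        def bwd(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, indices.reshape(-1), g.reshape(-1, self.data.shape[-1]))
            self._accum(acc)
        return Tensor(self.data[indices], parents=(self,), backward=bwd)

    def layer_norm(self, gain: "Tensor", bias: "Tensor", eps: float = 1e-5):
        """Layer normalization over the last axis (composed from primitives)."""
        mu = self.mean(axis=-1, keepdims=True)
        centered = self - mu
        var = centered.pow_const(2.0).mean(axis=-1, keepdims=True)
        inv = (var + eps).pow_const(-0.5)
        return centered * inv * gain + bias


def Parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


class Adam:
    """Adam optimizer over a dict of named parameter tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay and p.data.ndim > 1:  # decoupled; skip norms/biases
                p.data -= self.lr * self.weight_decay * p.data
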