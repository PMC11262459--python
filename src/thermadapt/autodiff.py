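"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operations the transformer encoder needs: broadcast
arithmetic, matrix products, tanh/relu/gelu, row softmax, layer
normalization, embedding lookup, basic indexing, reductions and the two
losses (softmax cross-entropy, mean squared error).  Gradients are
accumulated on a tape and released after ``backward``.

All arrays are float64; at the model sizes used here correctness and
reproducibility matter more than throughput.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np
from scipy.special import erf


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
        name: str = "",
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward
        self.name = name

    # -- plumbing -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def size(self) -> int:
        return self.data.size

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-topological backward pass from this tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node._parents:
                # free non-leaf grads and tape references
                if not node.requires_grad:
                    node.grad = None
                node._parents = ()
                node._backward = None

    # -- helpers ------------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _needs(self, *others: "Tensor") -> bool:
        return self.requires_grad or any(o.requires_grad for o in others)

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data + other.data
        a, b = self, other

        def bwd(g: np.ndarray) -> None:
            a._accumulate(_unbroadcast(g, a.shape))
            b._accumulate(_unbroadcast(g, b.shape))

        return Tensor(out_data, a._needs(b), (a, b), bwd)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        a = self

        def bwd(g: np.ndarray) -> None:
            a._accumulate(-g)

        return Tensor(-a.data, a.requires_grad, (a,), bwd)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        a, b = self, other

        def bwd(g: np.ndarray) -> None:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
            b._accumulate(_unbroadcast(g * a.data, b.shape))

        return Tensor(a.data * b.data, a._needs(b), (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._lift(other)
        a, b = self, other

        def bwd(g: np.ndarray) -> None:
            a._accumulate(_unbroadcast(g / b.data, a.shape))
            b._accumulate(_unbroadcast(-g * a.data / (b.data**2), b.shape))

        return Tensor(a.data / b.data, a._needs(b), (a, b), bwd)

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)
        a, b = self, other
        out_data = a.data @ b.data

        def bwd(g: np.ndarray) -> None:
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            a._accumulate(_unbroadcast(ga, a.shape))
            b._accumulate(_unbroadcast(gb, b.shape))

        return Tensor(out_data, a._needs(b), (a, b), bwd)

    def __getitem__(self, idx) -> "Tensor":
        a = self
        out_data = a.data[idx]

        def bwd(g: np.ndarray) -> None:
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accumulate(full)

        return Tensor(out_data, a.requires_grad, (a,), bwd)

    # -- shape ops ----------------------------------------------------------

    def reshape(self, *shape: int) -> "Tensor":
        a = self
        out_data = a.data.reshape(shape)

        def bwd(g: np.ndarray) -> None:
            a._accumulate(g.reshape(a.shape))

        return Tensor(out_data, a.requires_grad, (a,), bwd)

    def transpose(self, *axes: int) -> "Tensor":
        a = self
        inv = np.argsort(axes)

        def bwd(g: np.ndarray) -> None:
            a._accumulate(g.transpose(inv))

        return Tensor(a.data.transpose(axes), a.requires_grad, (a,), bwd)

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g: np.ndarray) -> None:
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.shape).copy())

        return Tensor(out_data, a.requires_grad, (a,), bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities -----------------------------------------------------

    def relu(self) -> "Tensor":
        a = self
        mask = a.data > 0

        def bwd(g: np.ndarray) -> None:
            a._accumulate(g * mask)

        return Tensor(a.data * mask, a.requires_grad, (a,), bwd)

    def tanh(self) -> "Tensor":
        a = self
        out_data = np.tanh(a.data)

        def bwd(g: np.ndarray) -> None:
            a._accumulate(g * (1.0 - out_data**2))

        return Tensor(out_data, a.requires_grad, (a,), bwd)

    def gelu(self) -> "Tensor":
        """Exact Gaussian-error-linear unit, x * Phi(x)."""
        a = self
        x = a.data
        phi = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        pdf = np.exp(-0.5 * x**2) / np.sqrt(2.0 * np.pi)
        out_data = x * phi

        def bwd(g: np.ndarray) -> None:
            a._accumulate(g * (phi + x * pdf))

        return Tensor(out_data, a.requires_grad, (a,), bwd)

    def softmax(self, axis: int = -1) -> "Tensor":
        a = self
        z = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def bwd(g: np.ndarray) -> None:
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            a._accumulate(out_data * (g - dot))

        return Tensor(out_data, a.requires_grad, (a,), bwd)

    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-12) -> "Tensor":
        """Normalize over the last axis, then scale and shift."""
        a = self
        mu = a.data.mean(axis=-1, keepdims=True)
        xc = a.data - mu
        var = (xc**2).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        out_data = gamma.data * xhat + beta.data
        n = a.data.shape[-1]

        def bwd(g: np.ndarray) -> None:
            gxhat = g * gamma.data
            dx = (
                inv
                / n
                * (
                    n * gxhat
                    - gxhat.sum(axis=-1, keepdims=True)
                    - xhat * (gxhat * xhat).sum(axis=-1, keepdims=True)
                )
            )
            a._accumulate(dx)
            gamma._accumulate(_unbroadcast(g * xhat, gamma.shape))
            beta._accumulate(_unbroadcast(g, beta.shape))

        return Tensor(out_data, a._needs(gamma, beta), (a, gamma, beta), bwd)


# -- free functions ---------------------------------------------------------


def embedding(table: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup ``table[ids]`` with scatter-add backward."""
    ids = np.asarray(ids, dtype=np.intp)
    out_data = table.data[ids]

    def bwd(g: np.ndarray) -> None:
        full = np.zeros_like(table.data)
        np.add.at(full, ids.reshape(-1), g.reshape(-1, table.data.shape[-1]))
        table._accumulate(full)

    return Tensor(out_data, table.requires_grad, (table,), bwd)


def cross_entropy_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy of (N, C) logits against int labels."""
    labels = np.asarray(labels, dtype=np.intp)
    n = logits.data.shape[0]
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - logsumexp
    loss = -logp[np.arange(n), labels].mean()
    probs = np.exp(logp)

    def bwd(g: np.ndarray) -> None:
        dz = probs.copy()
        dz[np.arange(n), labels] -= 1.0
        logits._accumulate(g * dz / n)

    return Tensor(loss, logits.requires_grad, (logits,), bwd)


def mse(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean squared error of predictions against a constant target."""
    target = np.asarray(target, dtype=np.float64)
    diff = pred.data - target
    loss = (diff**2).mean()

    def bwd(g: np.ndarray) -> None:
        pred._accumulate(g * 2.0 * diff / diff.size)

    return Tensor(loss, pred.requires_grad, (pred,), bwd)


class AdamW:
    """AdamW over a list of named parameter tensors.

    Defaults follow the common transformer-training configuration:
    betas (0.9, 0.999), eps 1e-8, decoupled weight decay 0.
    """

    def __init__(
        self,
        params: Iterable[tuple[str, Tensor]],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = {name: np.zeros_like(p.data) for name, p in self.params}
        self._v = {name: np.zeros_like(p.data) for name, p in self.params}

    def zero_grad(self) -> None:
        for _, p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for name, p in self.params:
            if p.grad is None:
                continue
            m = self._m[name]
            v = self._v[name]
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * p.grad**2
            update = (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            if self.weight_decay:
                update = update + self.weight_decay * p.data
            p.data -= self.lr * update
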