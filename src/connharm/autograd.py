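"""Minimal reverse-mode automatic differentiation on numpy arrays.

The networks used in this package are small dense stacks (a few tens of
thousands of parameters), so a compact tape-based engine is sufficient: each
:class:`Tensor` records its parents and a closure that accumulates gradients
into them.  Broadcasting follows numpy semantics; gradients of broadcast
operands are summed back to the original shape.

Only the operations the models need are implemented (affine maps, ReLU,
exp/log, reductions, row gathering, log-softmax).  Gradients flow to any
tensor created with ``requires_grad=True``, including *inputs* — which is how
integrated gradients are computed without a second code path.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "clip_global_norm", "no_grad"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes of size 1 that were stretched
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling graph construction (evaluation paths)."""

    def __enter__(self):
        self._prev = _GRAD_ENABLED[0]
        _GRAD_ENABLED[0] = False
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED[0] = self._prev
        return False


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED[0]
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _make(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if _GRAD_ENABLED[0] and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        g = _unbroadcast(g, self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(g)
            if b.requires_grad:
                b._accum(g)

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(g * b.data)
            if b.requires_grad:
                b._accum(g * a.data)

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(g / b.data)
            if b.requires_grad:
                b._accum(-g * a.data / (b.data**2))

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1))

        return Tensor._make(self.data**p, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(g @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ g)

        return Tensor._make(self.data @ other.data, (self, other), backward)

    # -- elementwise nonlinearities ------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g, a=self, od=out_data):
            if a.requires_grad:
                a._accum(g * od)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g / a.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g, a=self, m=mask):
            if a.requires_grad:
                a._accum(g * m)

        return Tensor._make(self.data * mask, (self,), backward)

    def softplus(self):
        # stable log(1 + exp(x)); gradient is the logistic sigmoid
        out_data = np.logaddexp(0.0, self.data)
        e = np.exp(-np.abs(self.data))
        sig = np.where(self.data >= 0, 1.0 / (1.0 + e), e / (1.0 + e))

        def backward(g, a=self, s=sig):
            if a.requires_grad:
                a._accum(g * s)

        return Tensor._make(out_data, (self,), backward)

    # -- reductions / reshaping ----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g, a=self):
            if not a.requires_grad:
                return
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.data.shape))

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def take_rows(self, idx: np.ndarray):
        """Gather rows (e.g. per-subject site parameters); grad scatters back."""
        idx = np.asarray(idx, dtype=np.intp)

        def backward(g, a=self, ix=idx):
            if a.requires_grad:
                buf = np.zeros_like(a.data)
                np.add.at(buf, ix, g)
                a._accum(buf)

        return Tensor._make(self.data[idx], (self,), backward)

    def log_softmax(self, axis=-1):
        m = self.data.max(axis=axis, keepdims=True)
        shifted = self.data - m
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True)) + m
        out_data = self.data - lse
        soft = np.exp(out_data)

        def backward(g, a=self, s=soft):
            if a.requires_grad:
                a._accum(g - s * g.sum(axis=axis, keepdims=True))

        return Tensor._make(out_data, (self,), backward)

    # -- backprop -------------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can exceed recursion depth
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def item(self) -> float:
        if self.data.size != 1:
            raise ValueError("item() requires a size-1 tensor")
        return float(self.data.reshape(()))

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def clip_global_norm(params: list[Tensor], max_norm: float) -> float:
    """Scale all gradients so their joint L2 norm is at most `max_norm`."""
    total = np.sqrt(sum(float((p.grad**2).sum()) for p in params if p.grad is not None))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return total


class Adam:
    """Adam with L2 weight decay added to the gradient (classic formulation)."""

    def __init__(self, params: list[Tensor], lr: float = 0.002,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
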