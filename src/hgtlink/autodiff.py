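"""Minimal reverse-mode automatic differentiation on numpy arrays.

The graph-transformer encoder and the pair-scoring decoder are trained end to
end, which requires gradients through gather/scatter message passing,
per-segment softmax, batch normalization and the usual dense algebra.  This
module provides exactly that: a :class:`Tensor` wrapping a float64 ndarray, a
tape of primitive operations with hand-written adjoints, a tiny ``Module``
system for parameter bookkeeping, the AdamW optimizer and a cosine-annealing
learning-rate schedule.

Gradients of every primitive are validated against central finite differences
in the test suite; float64 is used throughout so those checks are tight.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = [
    "Tensor",
    "concat",
    "gather",
    "segment_sum",
    "segment_softmax",
    "heads_matmul",
    "relu",
    "gelu",
    "sigmoid",
    "exp",
    "log",
    "power",
    "dropout",
    "Module",
    "Linear",
    "BatchNorm1d",
    "AdamW",
    "CosineAnnealingLR",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the autodiff tape.

    ``data`` is always a float64 ndarray.  ``requires_grad`` marks leaves that
    accumulate gradients; interior nodes propagate whenever any parent does.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # -- infrastructure ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative topo sort; deep tapes would blow the recursion limit
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
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operators ---------------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._wrap(other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor(self.data + other.data, _parents=(self, other), _backward=bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor(-self.data, _parents=(self,), _backward=bw)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor(self.data * other.data, _parents=(self, other), _backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * power(Tensor._wrap(other), -1.0)

    def __matmul__(self, other):
        other = Tensor._wrap(other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return Tensor(self.data @ other.data, _parents=(self, other), _backward=bw)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        return Tensor(self.data.reshape(shape), _parents=(self,), _backward=bw)

    def sum(self, axis=None, keepdims: bool = False):
        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.full_like(self.data, 1.0) * g)
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,), _backward=bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


# -- free functions --------------------------------------------------------

def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  _parents=tuple(tensors), _backward=bw)


def gather(x: Tensor, index: np.ndarray) -> Tensor:
    """Select rows ``x[index]`` along axis 0 (repeats allowed)."""
    index = np.asarray(index, dtype=np.intp)

    def bw(g):
        if x.requires_grad:
            out = np.zeros_like(x.data)
            np.add.at(out, index, g)
            x._accumulate(out)

    return Tensor(x.data[index], _parents=(x,), _backward=bw)


def segment_sum(x: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Scatter-add rows of ``x`` into ``num_segments`` buckets (axis 0)."""
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    out = np.zeros((num_segments,) + x.data.shape[1:])
    np.add.at(out, segment_ids, x.data)

    def bw(g):
        if x.requires_grad:
            x._accumulate(g[segment_ids])

    return Tensor(out, _parents=(x,), _backward=bw)


def segment_softmax(scores: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Softmax of ``scores`` within each segment, independently per column.

    Numerically stabilized by subtracting the per-segment maximum (a constant
    shift, so it does not enter the gradient).
    """
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    m = np.full((num_segments,) + scores.data.shape[1:], -np.inf)
    np.maximum.at(m, segment_ids, scores.data)
    shifted = scores + Tensor(-m[segment_ids])
    e = exp(shifted)
    denom = segment_sum(e, segment_ids, num_segments)
    return e * power(gather(denom, segment_ids), -1.0)


def heads_matmul(x: Tensor, w: Tensor) -> Tensor:
    """Per-head matrix product: ``(E, h, d1) @ (h, d1, d2) -> (E, h, d2)``."""

    def bw(g):
        if x.requires_grad:
            x._accumulate(np.einsum("ehk,hdk->ehd", g, w.data))
        if w.requires_grad:
            w._accumulate(np.einsum("ehd,ehk->hdk", x.data, g))

    return Tensor(np.einsum("ehd,hdk->ehk", x.data, w.data), _parents=(x, w), _backward=bw)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor(x.data * mask, _parents=(x,), _backward=bw)


def gelu(x: Tensor) -> Tensor:
    # exact form: x * Phi(x); gradient Phi(x) + x * phi(x)
    phi = np.exp(-0.5 * x.data**2) / np.sqrt(2.0 * np.pi)
    cdf = 0.5 * (1.0 + erf(x.data / np.sqrt(2.0)))

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * (cdf + x.data * phi))

    return Tensor(x.data * cdf, _parents=(x,), _backward=bw)


def sigmoid(x: Tensor) -> Tensor:
    s = np.where(x.data >= 0, 1.0 / (1.0 + np.exp(-np.abs(x.data))),
                 np.exp(-np.abs(x.data)) / (1.0 + np.exp(-np.abs(x.data))))

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * s * (1.0 - s))

    return Tensor(s, _parents=(x,), _backward=bw)


def exp(x: Tensor) -> Tensor:
    e = np.exp(x.data)

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * e)

    return Tensor(e, _parents=(x,), _backward=bw)


def log(x: Tensor) -> Tensor:
    def bw(g):
        if x.requires_grad:
            x._accumulate(g / x.data)

    return Tensor(np.log(x.data), _parents=(x,), _backward=bw)


def power(x: Tensor, p: float) -> Tensor:
    def bw(g):
        if x.requires_grad:
            x._accumulate(g * p * x.data ** (p - 1.0))

    return Tensor(x.data**p, _parents=(x,), _backward=bw)


def dropout(x: Tensor, p: float, rng: np.random.Generator, train: bool) -> Tensor:
    """Inverted dropout; identity in eval mode or at p=0."""
    if not train or p <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


# -- modules ---------------------------------------------------------------

class Module:
    """Parameter container with recursive named-parameter traversal."""

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        out = []
        for name, value in vars(self).items():
            path = f"{prefix}{name}"
            out.extend(_collect(path, value))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)} unexpected={sorted(extra)}")
        for k, t in own.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != t.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {t.data.shape}")
            t.data = arr.copy()


def _collect(path: str, value):
    if isinstance(value, Tensor):
        return [(path, value)] if value.requires_grad else []
    if isinstance(value, Module):
        return value.named_parameters(prefix=path + ".")
    if isinstance(value, dict):
        out = []
        for k, v in value.items():
            out.extend(_collect(f"{path}.{k}", v))
        return out
    if isinstance(value, (list, tuple)):
        out = []
        for i, v in enumerate(value):
            out.extend(_collect(f"{path}.{i}", v))
        return out
    return []


class Linear(Module):
    """Affine map ``x @ W + b`` with fan-in-scaled uniform initialization."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        bound = 1.0 / np.sqrt(d_in)
        self.weight = Tensor(rng.uniform(-bound, bound, size=(d_in, d_out)), requires_grad=True)
        self.bias = Tensor(rng.uniform(-bound, bound, size=(d_out,)), requires_grad=True) if bias \
            else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        return y + self.bias if self.bias is not None else y


class BatchNorm1d(Module):
    """Batch normalization over axis 0 with running statistics for eval.

    Train mode normalizes by batch moments and updates the running estimates
    (unbiased variance, momentum 0.1, as is conventional); eval mode uses the
    frozen running estimates so scoring is deterministic.
    """

    def __init__(self, d: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(d)
        self.running_var = np.ones(d)

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        if train:
            mu = x.mean(axis=0, keepdims=True)
            centered = x + (-mu)
            var = (centered * centered).mean(axis=0, keepdims=True)
            xhat = centered * power(var + self.eps, -0.5)
            n = x.shape[0]
            unbiased = var.data.squeeze(0) * (n / max(n - 1, 1))
            self.running_mean = (1 - self.momentum) * self.running_mean \
                + self.momentum * mu.data.squeeze(0)
            self.running_var = (1 - self.momentum) * self.running_var \
                + self.momentum * unbiased
        else:
            xhat = (x + Tensor(-self.running_mean)) * Tensor(
                1.0 / np.sqrt(self.running_var + self.eps))
        return xhat * self.gamma + self.beta


class AdamW(Module):
    """AdamW: Adam moments with decoupled weight decay."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-2):
        self._params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data) for p in self._params]
        self._v = [np.zeros_like(p.data) for p in self._params]
        self._t = 0

    def zero_grad(self) -> None:
        for p in self._params:
            p.zero_grad()

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self._params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self._t)
            vhat = v / (1 - b2**self._t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)


class CosineAnnealingLR:
    """lr(t) = lr_min + (lr0 - lr_min) * (1 + cos(pi t / T)) / 2, stepped per epoch."""

    def __init__(self, optimizer: AdamW, t_max: int, lr_min: float = 0.0):
        self.optimizer = optimizer
        self.t_max = max(t_max, 1)
        self.lr0 = optimizer.lr
        self.lr_min = lr_min
        self.t = 0

    def current_lr(self) -> float:
        return self.lr_min + 0.5 * (self.lr0 - self.lr_min) * (
            1.0 + np.cos(np.pi * self.t / self.t_max))

    def step(self) -> None:
        self.t = min(self.t + 1, self.t_max)
        self.optimizer.lr = self.current_lr()
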