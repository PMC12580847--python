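"""Minimal reverse-mode automatic differentiation and neural-net building blocks.

Everything operates on float64 NumPy arrays. The op set is deliberately small:
exactly what a message-passing network on a batched molecular graph needs
(broadcast arithmetic, matmul, axis reductions, row gather, segment scatter-add,
and a few pointwise nonlinearities). Gradients are checked against finite
differences in the test suite.
"""

from __future__ import annotations

import ctypes
from typing import Iterable, Sequence

import numpy as np

# Autodiff tapes keep many multi-megabyte temporaries alive, which defeats
# glibc's default mmap-based allocation for large blocks (every fresh block
# pays page-fault zeroing). Raising the mmap threshold keeps those blocks on
# the heap free-list; harmless no-op on non-glibc platforms.
try:
    ctypes.CDLL("libc.so.6").mallopt(-3, 1 << 30)  # M_MMAP_THRESHOLD
except Exception:  # pragma: no cover
    pass

__all__ = [
    "Tensor",
    "ensure",
    "parameter",
    "concat",
    "cols",
    "repeat_cols",
    "gather_rows",
    "gather_cols",
    "segment_sum",
    "segment_softmax",
    "Linear",
    "LayerNorm",
    "MLP",
    "Module",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """Node of the autodiff tape."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in self._parents)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    def backward(self) -> None:
        """Reverse sweep from this (scalar) node."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        while stack:
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen and p.requires_grad]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                stack.pop()
                if node.requires_grad:
                    topo.append(node)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ---- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = ensure(other)
        out = Tensor(self.data + other.data, (self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        out._backward = backward
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = ensure(other)
        out = Tensor(self.data * other.data, (self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-ensure(other))

    def __rsub__(self, other):
        return ensure(other) + (-self)

    def __truediv__(self, other):
        other = ensure(other)
        out = Tensor(self.data / other.data, (self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / (other.data ** 2))

        out._backward = backward
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, (self,))

        def backward(g):
            self._accum(g * p * self.data ** (p - 1))

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = ensure(other)
        a, b = self.data, other.data
        if b.ndim != 2:
            raise ValueError("matmul right operand must be 2-D")
        out = Tensor(a @ b, (self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(g @ b.T)
            if other.requires_grad:
                if a.ndim == 2:
                    other._accum(a.T @ g)
                else:  # (N, k, C) @ (C, D): accumulate over leading axes
                    axes = list(range(a.ndim - 1))
                    other._accum(np.tensordot(a, g, axes=(axes, axes)))

        out._backward = backward
        return out

    # ---- reductions / shape --------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))

        def backward(g):
            self._accum(g.reshape(self.data.shape))

        out._backward = backward
        return out

    def expand_dims(self, axis: int):
        return self.reshape(*np.expand_dims(self.data, axis).shape)

    # ---- pointwise nonlinearities --------------------------------------
    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, (self,))

        def backward(g):
            self._accum(g * val)

        out._backward = backward
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = Tensor(val, (self,))

        def backward(g):
            self._accum(g * 0.5 / val)

        out._backward = backward
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = Tensor(val, (self,))

        def backward(g):
            self._accum(g * (1.0 - val ** 2))

        out._backward = backward
        return out

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500.0, 500.0)))
        out = Tensor(val, (self,))

        def backward(g):
            self._accum(g * val * (1.0 - val))

        out._backward = backward
        return out

    def silu(self):
        sig = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500.0, 500.0)))
        out = Tensor(self.data * sig, (self,))

        def backward(g):
            self._accum(g * sig * (1.0 + self.data * (1.0 - sig)))

        out._backward = backward
        return out


def ensure(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [ensure(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out._backward = backward
    return out


def gather_rows(t: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx, dtype=np.intp)
    out = Tensor(t.data[idx], (t,))

    def backward(g):
        buf = np.zeros_like(t.data)
        np.add.at(buf, idx, g)
        t._accum(buf)

    out._backward = backward
    return out


def cols(t: Tensor, a: int, b: int) -> Tensor:
    """Contiguous column slice t[:, a:b] (cheap slice-assign backward)."""
    out = Tensor(t.data[:, a:b], (t,))

    def backward(g):
        buf = np.zeros_like(t.data)
        buf[:, a:b] = g
        t._accum(buf)

    out._backward = backward
    return out


def repeat_cols(t: Tensor, k: int) -> Tensor:
    """Repeat each column k times: (E, H) -> (E, H·k)."""
    e, h = t.data.shape
    out = Tensor(np.repeat(t.data, k, axis=1), (t,))

    def backward(g):
        t._accum(g.reshape(e, h, k).sum(axis=2))

    out._backward = backward
    return out


def gather_cols(t: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx, dtype=np.intp)
    out = Tensor(t.data[:, idx], (t,))

    def backward(g):
        buf = np.zeros_like(t.data)
        np.add.at(buf, (slice(None), idx), g)
        t._accum(buf)

    out._backward = backward
    return out


def segment_sum(t: Tensor, seg: np.ndarray, n_segments: int) -> Tensor:
    seg = np.asarray(seg, dtype=np.intp)
    val = np.zeros((n_segments,) + t.data.shape[1:])
    np.add.at(val, seg, t.data)
    out = Tensor(val, (t,))

    def backward(g):
        t._accum(g[seg])

    out._backward = backward
    return out


def segment_softmax(logits: Tensor, seg: np.ndarray, n_segments: int) -> Tensor:
    """Softmax of `logits` (E, H) normalized within segments of axis 0.

    The per-segment max subtracted for numerical stability is treated as a
    constant; softmax is shift-invariant so the gradient is exact.
    """
    seg = np.asarray(seg, dtype=np.intp)
    m = np.full((n_segments,) + logits.data.shape[1:], -np.inf)
    np.maximum.at(m, seg, logits.data)
    z = (logits - Tensor(m[seg])).exp()
    denom = segment_sum(z, seg, n_segments)
    return z / gather_rows(denom, seg)


# ---- modules ------------------------------------------------------------


class Module:
    """Tiny parameter-container base: recursive discovery over attributes."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def walk(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    walk(v)

        walk(self)
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: Iterable[np.ndarray]) -> None:
        params = self.parameters()
        arrays = list(arrays)
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch in checkpoint")
            p.data = np.asarray(a, dtype=np.float64)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, zero_init: bool = False):
        scale = 0.0 if zero_init else 1.0 / np.sqrt(n_in)
        self.weight = parameter(rng.standard_normal((n_in, n_out)) * scale)
        self.bias = parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    """Normalization over the last (feature) axis with learned scale/shift.

    Applied only to invariant scalar channels — normalizing steerable features
    per-component would break equivariance.
    """

    def __init__(self, dim: int, eps: float = 1e-6):
        self.gamma = parameter(np.ones(dim))
        self.beta = parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class MLP(Module):
    """Linear stack with SiLU activations between layers."""

    def __init__(self, dims: Sequence[int], rng: np.random.Generator):
        self.layers = [Linear(dims[i], dims[i + 1], rng) for i in range(len(dims) - 1)]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.silu()
        return x


class Adam:
    """Adam optimizer with bias correction."""

    def __init__(self, params: Sequence[Tensor], lr: float = 5e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
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
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
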