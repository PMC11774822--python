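"""Minimal reverse-mode autodiff and neural-network layers on NumPy.

Float64 throughout, which keeps runs bit-reproducible on one device and makes
exact no-leakage and determinism contracts testable.  The surface mirrors the
conventions of the mainstream deep-learning stacks at the scale this package
needs: Tensor with .backward(), Module/Parameter trees, Linear, LayerNorm,
Dropout, multi-head attention (exact softmax or positive-random-feature
linear attention), and Adam.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Linear",
    "LayerNorm",
    "Dropout",
    "MultiHeadSelfAttention",
    "TransformerBlock",
    "MLP",
    "Adam",
    "concat",
    "relu",
    "sigmoid",
    "softmax",
    "set_grad_enabled",
]

_GRAD_ENABLED = [True]


class set_grad_enabled:
    """Context manager disabling graph construction (inference mode)."""

    def __init__(self, mode: bool) -> None:
        self.mode = mode

    def __enter__(self):
        self.prev = _GRAD_ENABLED[0]
        _GRAD_ENABLED[0] = self.mode

    def __exit__(self, *exc):
        _GRAD_ENABLED[0] = self.prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _GRAD_ENABLED[0]
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple = ()

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED[0] and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor") -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is None:
                t.grad = g if t.grad is None else t.grad + g
                continue
            for p, pg in zip(t._parents, t._backward(g)):
                if not p.requires_grad or pg is None:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    # -- shape info --------------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        return self._make(
            self.data + other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g, self.data.shape),
                _unbroadcast(g, other.data.shape),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        return self._make(
            self.data * other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._lift(other).pow(-1.0)

    def __rtruediv__(self, other):
        return self._lift(other) * self.pow(-1.0)

    def pow(self, exponent: float):
        out_data = self.data**exponent
        return self._make(
            out_data,
            (self,),
            lambda g: (g * exponent * self.data ** (exponent - 1.0),),
        )

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return (
                _unbroadcast(ga, self.data.shape),
                _unbroadcast(gb, other.data.shape),
            )

        return self._make(self.data @ other.data, (self, other), backward)

    def exp(self):
        out_data = np.exp(self.data)
        return self._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return self._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.data.shape).copy(),)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        orig = self.data.shape
        return self._make(
            self.data.reshape(*shape), (self,), lambda g: (g.reshape(orig),)
        )

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return self._make(
            self.data.transpose(*axes), (self,), lambda g: (g.transpose(*inv),)
        )

    def take_rows(self, idx: np.ndarray):
        """Gather rows (first axis) by an integer index array (embedding lookup)."""
        idx = np.asarray(idx)

        def backward(g):
            out = np.zeros_like(self.data)
            np.add.at(out, idx.reshape(-1), g.reshape(-1, *self.data.shape[1:]))
            return (out,)

        return self._make(self.data[idx], (self,), backward)

    def item(self) -> float:
        return float(self.data)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    out = tensors[0]._make(data, tuple(tensors), backward)
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return x._make(x.data * mask, (x,), lambda g: (g * mask,))


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    return x._make(s, (x,), lambda g: (g * s * (1.0 - s),))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    # shift by a detached max; softmax is shift-invariant so gradients are exact
    shifted = x + Tensor(-x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        self.requires_grad = True  # parameters stay trainable even in no-grad blocks


class Module:
    def parameters(self) -> list:
        params: list[Parameter] = []
        seen: set[int] = set()
        stack: list = [self]
        while stack:
            obj = stack.pop()
            for value in vars(obj).values():
                if isinstance(value, Parameter) and id(value) not in seen:
                    seen.add(id(value))
                    params.append(value)
                elif isinstance(value, Module):
                    stack.append(value)
                elif isinstance(value, (list, tuple)):
                    stack.extend(v for v in value if isinstance(v, Module))
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> list:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: Iterable[np.ndarray]) -> None:
        for p, d in zip(self.parameters(), state, strict=True):
            p.data = d.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        scale = math.sqrt(2.0 / (in_dim + out_dim))
        self.weight = Parameter(rng.normal(0.0, scale, size=(in_dim, out_dim)))
        self.bias = Parameter(np.zeros(out_dim))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gain = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        inv = (var + self.eps).pow(-0.5)
        return centered * inv * self.gain + self.bias


class Dropout(Module):
    """Inverted dropout driven by an explicit generator; identity when p=0 or eval."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0 <= p < 1:
            raise ValueError("dropout p must lie in [0, 1)")
        self.p = p
        self.rng = rng
        self.training = True

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(keep)


class MultiHeadSelfAttention(Module):
    """Self-attention over the token axis; no positional order is assumed.

    ``backend='exact'`` is standard softmax attention.  ``backend='performer'``
    uses the positive-random-feature approximation of the softmax kernel,
    giving cost linear in sequence length; the feature matrix is drawn once at
    construction from ``rng`` and kept fixed.
    """

    def __init__(
        self,
        d_model: int,
        n_heads: int,
        rng: np.random.Generator,
        backend: str = "exact",
        n_features: int = 128,
    ):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if backend not in ("exact", "performer"):
            raise ValueError(f"unknown attention backend {backend!r}")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.backend = backend
        self.q = Linear(d_model, d_model, rng)
        self.k = Linear(d_model, d_model, rng)
        self.v = Linear(d_model, d_model, rng)
        self.out = Linear(d_model, d_model, rng)
        if backend == "performer":
            self.omega = Tensor(rng.normal(size=(n_heads, self.d_head, n_features)))

    def _split(self, x: Tensor, B: int, L: int) -> Tensor:
        # (B, L, d_model) -> (B, H, L, d_head)
        return x.reshape(B, L, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def forward(self, x: Tensor, key_mask: np.ndarray | None = None) -> Tensor:
        """key_mask: bool (B, L); False positions are excluded as attention keys."""
        B, L, D = x.shape
        q = self._split(self.q(x), B, L)
        k = self._split(self.k(x), B, L)
        v = self._split(self.v(x), B, L)
        if self.backend == "exact":
            scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(self.d_head))
            if key_mask is not None:
                bias = np.where(key_mask, 0.0, -1e9)[:, None, None, :]
                scores = scores + Tensor(bias)
            attn = softmax(scores, axis=-1)
            ctx = attn @ v
        else:
            ctx = self._performer(q, k, v, key_mask)
        ctx = ctx.transpose(0, 2, 1, 3).reshape(B, L, D)
        return self.out(ctx)

    def _performer(self, q: Tensor, k: Tensor, v: Tensor, key_mask) -> Tensor:
        m = self.omega.shape[-1]
        scale = self.d_head ** -0.25

        def phi(t: Tensor) -> Tensor:
            ts = t * scale
            proj = ts @ self.omega  # (B, H, L, m)
            sq = (ts * ts).sum(axis=-1, keepdims=True) * 0.5
            return (proj - sq).exp() * (1.0 / math.sqrt(m))

        qf, kf = phi(q), phi(k)
        if key_mask is not None:
            kf = kf * Tensor(key_mask[:, None, :, None].astype(float))
        kv = kf.transpose(0, 1, 3, 2) @ v  # (B, H, m, d_head)
        num = qf @ kv
        den = qf @ kf.sum(axis=2, keepdims=True).transpose(0, 1, 3, 2)
        return num / (den + 1e-12)


class TransformerBlock(Module):
    """Pre-LayerNorm transformer block (attention + position-wise feed-forward)."""

    def __init__(
        self,
        d_model: int,
        n_heads: int,
        rng: np.random.Generator,
        ffn_mult: int = 4,
        dropout: float = 0.0,
        backend: str = "exact",
        n_features: int = 128,
    ):
        self.ln1 = LayerNorm(d_model)
        self.attn = MultiHeadSelfAttention(d_model, n_heads, rng, backend, n_features)
        self.ln2 = LayerNorm(d_model)
        self.ff1 = Linear(d_model, ffn_mult * d_model, rng)
        self.ff2 = Linear(ffn_mult * d_model, d_model, rng)
        self.drop = Dropout(dropout, rng)

    def forward(self, x: Tensor, key_mask: np.ndarray | None = None) -> Tensor:
        x = x + self.drop(self.attn(self.ln1(x), key_mask))
        x = x + self.drop(self.ff2(relu(self.ff1(self.ln2(x)))))
        return x


class MLP(Module):
    """Stack of Linear layers with LayerNorm + ReLU + Dropout between them."""

    def __init__(self, widths: Sequence[int], rng: np.random.Generator, dropout: float = 0.0):
        if len(widths) < 2:
            raise ValueError("MLP needs at least input and output widths")
        self.layers = [Linear(a, b, rng) for a, b in zip(widths[:-1], widths[1:])]
        self.norms = [LayerNorm(b) for b in widths[1:-1]]
        self.drop = Dropout(dropout, rng)

    def forward(self, x: Tensor) -> Tensor:
        for layer, norm in zip(self.layers[:-1], self.norms):
            x = self.drop(relu(norm(layer(x))))
        return self.layers[-1](x)

    @property
    def training(self) -> bool:
        return self.drop.training

    @training.setter
    def training(self, mode: bool) -> None:
        self.drop.training = mode


class Adam:
    def __init__(
        self,
        params: Sequence[Parameter],
        lr: float = 1e-3,
        betas: tuple = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
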