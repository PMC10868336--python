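"""Minimal reverse-mode autodiff and neural-network layers on numpy.

Supports exactly the operations the encoder/decoder/classifier stack needs:
broadcast add/mul, batched matmul, reshape/transpose/slice, embedding
lookup, softmax, layer norm, GELU, dropout, and fused softmax
cross-entropy.  Gradients flow through a dynamically built tape; `backward`
topologically sorts it.  Everything is float64-free by design: parameters
and activations are float32 for speed, loss reductions happen in float64.
"""
from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import erf

__all__ = [
    "Tensor", "Parameter", "Linear", "Embedding", "LayerNorm",
    "MultiHeadAttention", "FeedForward", "EncoderLayer", "AdamW",
    "softmax", "gelu", "cross_entropy_logits", "dropout",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the tape machinery to backprop through it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple["Tensor", ...] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # ---- graph plumbing -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.ones_like(self.data) if grad is None
                    else np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ---- ops ------------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))
        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, scalar: float) -> "Tensor":
        return self * (1.0 / float(scalar))

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out = Tensor(np.matmul(self.data, other.data), parents=(self, other))
        a, b = self.data, other.data

        def bwd(g):
            ga = np.matmul(g, np.swapaxes(b, -1, -2))
            gb = np.matmul(np.swapaxes(a, -1, -2), g)
            self._accum(_unbroadcast(ga, a.shape))
            other._accum(_unbroadcast(gb, b.shape))
        out._backward = bwd
        return out

    __matmul__ = matmul

    def reshape(self, *shape: int) -> "Tensor":
        orig = self.data.shape
        out = Tensor(self.data.reshape(shape), parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(orig))
        return out

    def transpose(self, *axes: int) -> "Tensor":
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))
        out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], parents=(self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)
        out._backward = bwd
        return out

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     parents=(self,))

        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())
        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self._accum(g * (1.0 - y * y))
        return out


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, parents=(x,))

    def bwd(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accum((g - dot) * s)
    out._backward = bwd
    return out


_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


def gelu(x: Tensor) -> Tensor:
    xd = x.data.astype(np.float64)
    phi = 0.5 * (1.0 + erf(xd / _SQRT2))
    out = Tensor(xd * phi, parents=(x,))

    def bwd(g):
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * xd * xd)
        x._accum((g * (phi + xd * pdf)).astype(np.float32))
    out._backward = bwd
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= p).astype(np.float32) / (1.0 - p)
    out = Tensor(x.data * keep, parents=(x,))
    out._backward = lambda g: x._accum(g * keep)
    return out


def cross_entropy_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer `targets` under row-wise softmax.

    `logits` is (M, V); rows correspond one-to-one with targets (callers
    pre-select masked positions / examples).
    """
    targets = np.asarray(targets)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=-1))
    m = targets.shape[0]
    nll = logsumexp - z[np.arange(m), targets]
    out = Tensor(np.float64(nll.mean()), parents=(logits,))

    def bwd(g):
        p = np.exp(z - logsumexp[:, None])
        p[np.arange(m), targets] -= 1.0
        logits._accum(g * p / m)
    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Module:
    def parameters(self) -> list[tuple[str, Parameter]]:
        params: list[tuple[str, Parameter]] = []
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                params.append((name, val))
            elif isinstance(val, Module):
                params.extend((f"{name}.{k}", p) for k, p in val.parameters())
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        params.extend((f"{name}.{i}.{k}", p)
                                      for k, p in item.parameters())
        return params

    def zero_grad(self) -> None:
        for _, p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], dtype=np.float32).copy()


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        if zero_init:
            w = np.zeros((d_in, d_out))
        else:
            w = rng.normal(0.0, math.sqrt(2.0 / (d_in + d_out)), (d_in, d_out))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    def __init__(self, n_vocab: int, d_model: int, rng: np.random.Generator):
        self.weight = Parameter(rng.normal(0.0, 0.02, (n_vocab, d_model)))

    def __call__(self, ids: np.ndarray) -> Tensor:
        w = self.weight
        out = Tensor(w.data[ids], parents=(w,))

        def bwd(g):
            full = np.zeros_like(w.data)
            np.add.at(full, ids.reshape(-1),
                      g.reshape(-1, w.data.shape[1]))
            w._accum(full)
        out._backward = bwd
        return out


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(d))
        self.beta = Parameter(np.zeros(d))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        xd = x.data.astype(np.float64)
        mu = xd.mean(axis=-1, keepdims=True)
        var = xd.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (xd - mu) * inv
        g_, b_ = self.gamma, self.beta
        out = Tensor(xhat * g_.data + b_.data, parents=(x, g_, b_))
        d = xd.shape[-1]

        def bwd(g):
            g = g.astype(np.float64)
            g_._accum((g * xhat).sum(axis=tuple(range(g.ndim - 1))).astype(np.float32))
            b_._accum(g.sum(axis=tuple(range(g.ndim - 1))).astype(np.float32))
            gx = g * g_.data.astype(np.float64)
            dx = inv * (gx - gx.mean(axis=-1, keepdims=True)
                        - xhat * (gx * xhat).mean(axis=-1, keepdims=True))
            x._accum(dx.astype(np.float32))
        out._backward = bwd
        return out


class MultiHeadAttention(Module):
    """Scaled dot-product attention; self- or cross- depending on inputs."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)

    def __call__(self, query: Tensor, kv: Tensor,
                 key_pad_bias: np.ndarray | None = None) -> Tensor:
        B, Nq, D = query.shape
        Nk = kv.shape[1]
        h, dh = self.n_heads, self.d_head

        def split(t: Tensor, n: int) -> Tensor:
            return t.reshape(B, n, h, dh).transpose(0, 2, 1, 3)

        q = split(self.wq(query), Nq)
        k = split(self.wk(kv), Nk)
        v = split(self.wv(kv), Nk)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dh))
        if key_pad_bias is not None:           # (B, 1, 1, Nk), -inf-ish on pads
            scores = scores + Tensor(key_pad_bias)
        attn = softmax(scores, axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, Nq, D)
        return self.wo(ctx)


class FeedForward(Module):
    def __init__(self, d_model: int, d_ff: int, rng: np.random.Generator):
        self.w1 = Linear(d_model, d_ff, rng)
        self.w2 = Linear(d_ff, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.w2(gelu(self.w1(x)))


class EncoderLayer(Module):
    """Pre-norm transformer block: x + MHA(LN(x)); x + FFN(LN(x))."""

    def __init__(self, d_model: int, n_heads: int, d_ff: int,
                 rng: np.random.Generator):
        self.ln1 = LayerNorm(d_model)
        self.attn = MultiHeadAttention(d_model, n_heads, rng)
        self.ln2 = LayerNorm(d_model)
        self.ff = FeedForward(d_model, d_ff, rng)

    def __call__(self, x: Tensor, pad_bias: np.ndarray | None) -> Tensor:
        h = self.ln1(x)
        x = x + self.attn(h, h, pad_bias)
        return x + self.ff(self.ln2(x))


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params: Sequence[tuple[str, Parameter]],
                 lr: float = 1e-3, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in self.params}
        self._v = {k: np.zeros_like(p.data) for k, p in self.params}

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, p in self.params:
            if p.grad is None:
                continue
            g = p.grad
            m = self._m[k]
            v = self._v[k]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay:
                update = update + self.weight_decay * p.data
            p.data -= self.lr * update

    def zero_grad(self) -> None:
        for _, p in self.params:
            p.grad = None
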