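"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the tensor operations, layers and optimizer the haplotype
model needs: broadcast arithmetic, batched matmul, fused linear / layer-norm /
GeLU / scaled-dot-product-attention / cross-entropy kernels, an ``AdamW``
optimizer and a tiny ``Module`` system.  Everything runs in float32.
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
    "Embedding",
    "MultiheadAttention",
    "TransformerEncoderLayer",
    "TransformerDecoderLayer",
    "AdamW",
    "linear",
    "layer_norm",
    "gelu",
    "sdpa",
    "cross_entropy_logits",
    "embedding_lookup",
    "dropout",
    "concat",
    "softmax",
]


def _as_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=np.float32)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum-reduce ``grad`` back to ``shape`` after numpy broadcasting."""
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
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward: Callable | None = None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # ---- graph -----------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that requires no grad")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar output")
            grad = np.ones_like(self.data)
        self.grad = _as_array(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    # ---- basic ops -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    def __neg__(self):
        return self * Tensor(-1.0)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    __radd__ = __add__
    __rmul__ = __mul__

    def matmul(self, other: "Tensor") -> "Tensor":
        out_data = np.matmul(self.data, other.data)

        def bwd(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __matmul__ = matmul

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src_shape = self.data.shape
        out_data = self.data.reshape(shape)

        def bwd(g):
            self._accum(g.reshape(src_shape))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def bwd(g):
            self._accum(g.transpose(inv))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        src_shape = self.data.shape

        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, src_shape).astype(np.float32))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, src_shape).astype(np.float32))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * Tensor(1.0 / n)

    def item(self) -> float:
        return float(self.data)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# ---- fused kernels --------------------------------------------------------

def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """``x @ w + b`` with ``x`` of shape [..., in], ``w`` [in, out]."""
    out_data = x.data @ w.data
    if b is not None:
        out_data = out_data + b.data

    def bwd(g):
        g2 = g.reshape(-1, g.shape[-1])
        if x.requires_grad:
            x._accum((g @ w.data.T).reshape(x.data.shape))
        if w.requires_grad:
            x2 = x.data.reshape(-1, x.data.shape[-1])
            w._accum(x2.T @ g2)
        if b is not None and b.requires_grad:
            b._accum(g2.sum(axis=0))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out_data, parents=parents, backward=bwd)


_GELU_C = math.sqrt(2.0 / math.pi)


def gelu(x: Tensor) -> Tensor:
    """GeLU activation (tanh approximation)."""
    xd = x.data
    inner = _GELU_C * (xd + 0.044715 * xd ** 3)
    t = np.tanh(inner)
    out_data = 0.5 * xd * (1.0 + t)

    def bwd(g):
        dinner = _GELU_C * (1.0 + 3 * 0.044715 * xd ** 2)
        dx = 0.5 * (1.0 + t) + 0.5 * xd * (1.0 - t ** 2) * dinner
        x._accum(g * dx)

    return Tensor(out_data, parents=(x,), backward=bwd)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc ** 2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = gamma.data * xhat + beta.data

    def bwd(g):
        if gamma.requires_grad:
            gamma._accum(_unbroadcast(g * xhat, gamma.data.shape))
        if beta.requires_grad:
            beta._accum(_unbroadcast(g, beta.data.shape))
        if x.requires_grad:
            dxhat = g * gamma.data
            m1 = dxhat.mean(axis=-1, keepdims=True)
            m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
            x._accum(inv * (dxhat - m1 - xhat * m2))

    return Tensor(out_data, parents=(x, gamma, beta), backward=bwd)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    e = np.exp(x.data - m)
    s = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accum(s * (g - dot))

    return Tensor(s, parents=(x,), backward=bwd)


def sdpa(q: Tensor, k: Tensor, v: Tensor,
         mask: np.ndarray | None = None) -> Tensor:
    """Scaled dot-product attention on [B, H, T, head_dim] tensors.

    ``mask`` is an additive float array broadcastable to [B, H, Tq, Tk]
    (0 where attention is allowed, a large negative number where not).
    """
    hd = q.data.shape[-1]
    scale = 1.0 / math.sqrt(hd)
    scores = np.matmul(q.data, np.swapaxes(k.data, -1, -2)) * scale
    if mask is not None:
        scores = scores + mask
    m = scores.max(axis=-1, keepdims=True)
    e = np.exp(scores - m)
    attn = e / e.sum(axis=-1, keepdims=True)
    out_data = np.matmul(attn, v.data)

    def bwd(g):
        if v.requires_grad:
            v._accum(np.matmul(np.swapaxes(attn, -1, -2), g))
        dattn = np.matmul(g, np.swapaxes(v.data, -1, -2))
        ds = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
        ds *= scale
        if q.requires_grad:
            q._accum(np.matmul(ds, k.data))
        if k.requires_grad:
            k._accum(np.matmul(np.swapaxes(ds, -1, -2), q.data))

    return Tensor(out_data, parents=(q, k, v), backward=bwd)


def cross_entropy_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Per-example cross-entropy.  ``logits`` [N, V], ``targets`` int [N]."""
    ld = logits.data
    t = np.asarray(targets, dtype=np.int64)
    m = ld.max(axis=-1, keepdims=True)
    z = ld - m
    lse = np.log(np.exp(z).sum(axis=-1)) + m[:, 0]
    picked = ld[np.arange(ld.shape[0]), t]
    out_data = lse - picked

    def bwd(g):
        p = np.exp(ld - m)
        p /= p.sum(axis=-1, keepdims=True)
        p[np.arange(ld.shape[0]), t] -= 1.0
        logits._accum(p * g[:, None])

    return Tensor(out_data, parents=(logits,), backward=bwd)


def embedding_lookup(weight: Tensor, ids: np.ndarray) -> Tensor:
    ids = np.asarray(ids, dtype=np.int64)
    out_data = weight.data[ids]

    def bwd(g):
        gw = np.zeros_like(weight.data)
        np.add.at(gw, ids.reshape(-1), g.reshape(-1, g.shape[-1]))
        weight._accum(gw)

    return Tensor(out_data, parents=(weight,), backward=bwd)


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= p).astype(np.float32) / (1.0 - p)
    return x * Tensor(keep)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor(out_data, parents=tuple(tensors), backward=bwd)


# ---- modules ---------------------------------------------------------------

class Module:
    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        stack = [self]
        while stack:
            obj = stack.pop()
            for value in vars(obj).values():
                if isinstance(value, Parameter):
                    if id(value) not in seen:
                        seen.add(id(value))
                        params.append(value)
                elif isinstance(value, Module):
                    stack.append(value)
                elif isinstance(value, (list, tuple)):
                    stack.extend(v for v in value if isinstance(v, Module))
        return params

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                out.append((key, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(prefix=key + "."))
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        out.extend(v.named_parameters(prefix=f"{key}.{i}."))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True):
        bound = math.sqrt(6.0 / (n_in + n_out))
        self.weight = Parameter(rng.uniform(-bound, bound, size=(n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return linear(x, self.weight, self.bias)


class LayerNorm(Module):
    def __init__(self, dim: int):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta)


class Embedding(Module):
    def __init__(self, n_vocab: int, dim: int, rng: np.random.Generator):
        self.weight = Parameter(rng.normal(0.0, 0.02, size=(n_vocab, dim)))

    def __call__(self, ids: np.ndarray) -> Tensor:
        return embedding_lookup(self.weight, ids)


class MultiheadAttention(Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError("model dim must be divisible by head count")
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.q_proj = Linear(dim, dim, rng)
        self.k_proj = Linear(dim, dim, rng)
        self.v_proj = Linear(dim, dim, rng)
        self.out_proj = Linear(dim, dim, rng)

    def _split(self, x: Tensor) -> Tensor:
        b, t, _ = x.shape
        return x.reshape(b, t, self.n_heads, self.head_dim).transpose(0, 2, 1, 3)

    def __call__(self, query: Tensor, key: Tensor, value: Tensor,
                 mask: np.ndarray | None = None) -> Tensor:
        b, tq, dim = query.shape
        q = self._split(self.q_proj(query))
        k = self._split(self.k_proj(key))
        v = self._split(self.v_proj(value))
        out = sdpa(q, k, v, mask=mask)
        out = out.transpose(0, 2, 1, 3).reshape(b, tq, dim)
        return self.out_proj(out)


class _FeedForward(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(gelu(self.fc1(x)))


class TransformerEncoderLayer(Module):
    """Post-norm transformer encoder layer with GeLU feed-forward."""

    def __init__(self, dim: int, n_heads: int, ff_dim: int,
                 dropout_p: float, rng: np.random.Generator):
        self.self_attn = MultiheadAttention(dim, n_heads, rng)
        self.ff = _FeedForward(dim, ff_dim, rng)
        self.norm1 = LayerNorm(dim)
        self.norm2 = LayerNorm(dim)
        self.dropout_p = dropout_p

    def __call__(self, x: Tensor, rng: np.random.Generator,
                 training: bool) -> Tensor:
        a = self.self_attn(x, x, x)
        x = self.norm1(x + dropout(a, self.dropout_p, rng, training))
        f = self.ff(x)
        return self.norm2(x + dropout(f, self.dropout_p, rng, training))


class TransformerDecoderLayer(Module):
    """Post-norm decoder layer: causal self-attention + cross-attention."""

    def __init__(self, dim: int, n_heads: int, ff_dim: int,
                 dropout_p: float, rng: np.random.Generator):
        self.self_attn = MultiheadAttention(dim, n_heads, rng)
        self.cross_attn = MultiheadAttention(dim, n_heads, rng)
        self.ff = _FeedForward(dim, ff_dim, rng)
        self.norm1 = LayerNorm(dim)
        self.norm2 = LayerNorm(dim)
        self.norm3 = LayerNorm(dim)
        self.dropout_p = dropout_p

    def __call__(self, x: Tensor, memory: Tensor, causal_mask: np.ndarray,
                 rng: np.random.Generator, training: bool) -> Tensor:
        a = self.self_attn(x, x, x, mask=causal_mask)
        x = self.norm1(x + dropout(a, self.dropout_p, rng, training))
        c = self.cross_attn(x, memory, memory)
        x = self.norm2(x + dropout(c, self.dropout_p, rng, training))
        f = self.ff(x)
        return self.norm3(x + dropout(f, self.dropout_p, rng, training))


def causal_mask(t: int) -> np.ndarray:
    """Additive causal mask [1, 1, t, t] for self-attention."""
    m = np.triu(np.full((t, t), -1e9, dtype=np.float32), k=1)
    return m[None, None]


class AdamW:
    """AdamW with decoupled weight decay.

    Weight decay is skipped for 1-D parameters (biases, layer-norm gains),
    matching common transformer practice.
    """

    def __init__(self, params: Iterable[Parameter], lr: float = 5e-5,
                 betas: tuple[float, float] = (0.9, 0.99), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay and p.data.ndim > 1:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * update

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def clip_grad_norm(params: Iterable[Parameter], max_norm: float) -> float:
    """Scale gradients in place so their global L2 norm is at most max_norm."""
    params = [p for p in params if p.grad is not None]
    total = math.sqrt(sum(float((p.grad ** 2).sum()) for p in params))
    if total > max_norm > 0:
        scale = max_norm / (total + 1e-12)
        for p in params:
            p.grad *= scale
    return total
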