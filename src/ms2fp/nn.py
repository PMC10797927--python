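"""Minimal NumPy neural-network layers with explicit backpropagation.

Implements exactly the pieces the spectrum-to-fingerprint transformer needs:
dense and embedding layers, layer normalization, dropout, scaled dot-product
multi-head attention, and the Adam optimizer. Every layer performs one forward
pass, caches what its backward pass needs, and accumulates parameter gradients
into per-layer ``grads`` arrays. Gradient correctness is established by
finite-difference tests rather than by construction, so the implementations
stay direct and readable.

All parameters are float64; masks are additive (0 for admissible positions,
a large negative number for masked ones).
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

NEG_INF = -1e9


class Layer:
    """Base class: parameter/gradient registry plus child traversal."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.children: list[tuple[str, "Layer"]] = []

    def add_param(self, name: str, value: np.ndarray) -> np.ndarray:
        value = np.asarray(value, dtype=np.float64)
        self.params[name] = value
        self.grads[name] = np.zeros_like(value)
        return value

    def add_child(self, name: str, child: "Layer") -> "Layer":
        self.children.append((name, child))
        return child

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray, np.ndarray]]:
        for name, value in self.params.items():
            yield f"{prefix}{name}", value, self.grads[name]
        for child_name, child in self.children:
            yield from child.named_parameters(prefix=f"{prefix}{child_name}.")

    def zero_grad(self):
        for grad in self.grads.values():
            grad[...] = 0.0
        for _, child in self.children:
            child.zero_grad()

    def n_parameters(self) -> int:
        return sum(value.size for _, value, _ in self.named_parameters())


class Dense(Layer):
    """Affine map y = x W + b over the last axis."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        limit = math.sqrt(6.0 / (d_in + d_out))
        self.W = self.add_param("W", rng.uniform(-limit, limit, size=(d_in, d_out)))
        self.b = self.add_param("b", np.zeros(d_out))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self.W.shape[0])
        g2 = g.reshape(-1, self.W.shape[1])
        self.grads["W"] += x2.T @ g2
        self.grads["b"] += g2.sum(axis=0)
        return (g2 @ self.W.T).reshape(self._x.shape)


class Embedding(Layer):
    """Token-id lookup table."""

    def __init__(self, n_vocab: int, d_model: int, rng: np.random.Generator):
        super().__init__()
        self.table = self.add_param(
            "table", rng.normal(0.0, 1.0 / math.sqrt(d_model), size=(n_vocab, d_model))
        )
        self._ids: np.ndarray | None = None

    def forward(self, ids: np.ndarray) -> np.ndarray:
        ids = np.asarray(ids)
        if ids.max(initial=0) >= self.table.shape[0] or ids.min(initial=0) < 0:
            raise IndexError(
                f"token id out of vocabulary (size {self.table.shape[0]})"
            )
        self._ids = ids
        return self.table[ids]

    def backward(self, g: np.ndarray) -> None:
        np.add.at(self.grads["table"], self._ids, g)


class LayerNorm(Layer):
    """Normalization over the last axis with learned scale and shift."""

    def __init__(self, d_model: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = self.add_param("gamma", np.ones(d_model))
        self.beta = self.add_param("beta", np.zeros(d_model))
        self.eps = eps
        self._xhat: np.ndarray | None = None
        self._inv: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._xhat, self._inv = xhat, inv
        return self.gamma * xhat + self.beta

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        self.grads["gamma"] += (g * xhat).sum(axis=tuple(range(g.ndim - 1)))
        self.grads["beta"] += g.sum(axis=tuple(range(g.ndim - 1)))
        d = g.shape[-1]
        dxhat = g * self.gamma
        return (
            inv
            / d
            * (
                d * dxhat
                - dxhat.sum(axis=-1, keepdims=True)
                - xhat * (dxhat * xhat).sum(axis=-1, keepdims=True)
            )
        )


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, rng: np.random.Generator | None, train: bool) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return g
        return g * self._mask


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    shifted = x - x.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


class MultiHeadAttention(Layer):
    """Scaled dot-product attention with separate Q/K/V/output projections."""

    def __init__(self, d_model: int, n_heads: int, dropout: float, rng: np.random.Generator):
        super().__init__()
        if d_model % n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.q_proj = self.add_child("q_proj", Dense(d_model, d_model, rng))
        self.k_proj = self.add_child("k_proj", Dense(d_model, d_model, rng))
        self.v_proj = self.add_child("v_proj", Dense(d_model, d_model, rng))
        self.out_proj = self.add_child("out_proj", Dense(d_model, d_model, rng))
        self.attn_dropout = self.add_child("attn_dropout", Dropout(dropout))
        self._cache = None

    def _split(self, x: np.ndarray) -> np.ndarray:
        b, length, _ = x.shape
        return x.reshape(b, length, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        b, _, length, _ = x.shape
        return x.transpose(0, 2, 1, 3).reshape(b, length, self.n_heads * self.d_head)

    def forward(
        self,
        q_in: np.ndarray,
        k_in: np.ndarray,
        v_in: np.ndarray,
        mask: np.ndarray | None,
        rng: np.random.Generator | None,
        train: bool,
    ) -> np.ndarray:
        q = self._split(self.q_proj.forward(q_in))
        k = self._split(self.k_proj.forward(k_in))
        v = self._split(self.v_proj.forward(v_in))
        scores = q @ k.swapaxes(-1, -2) / math.sqrt(self.d_head)
        if mask is not None:
            scores = scores + mask
        attn = softmax(scores)
        attn_d = self.attn_dropout.forward(attn, rng, train)
        context = attn_d @ v
        self._cache = (q, k, v, attn, attn_d)
        return self.out_proj.forward(self._merge(context))

    def backward(self, g: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        q, k, v, attn, attn_d = self._cache
        d_context = self._split(self.out_proj.backward(g))
        d_attn_d = d_context @ v.swapaxes(-1, -2)
        dv = attn_d.swapaxes(-1, -2) @ d_context
        d_attn = self.attn_dropout.backward(d_attn_d)
        d_scores = attn * (d_attn - (d_attn * attn).sum(axis=-1, keepdims=True))
        d_scores /= math.sqrt(self.d_head)
        dq = d_scores @ k
        dk = d_scores.swapaxes(-1, -2) @ q
        dq_in = self.q_proj.backward(self._merge(dq))
        dk_in = self.k_proj.backward(self._merge(dk))
        dv_in = self.v_proj.backward(self._merge(dv))
        return dq_in, dk_in, dv_in


class FeedForward(Layer):
    """Position-wise two-layer MLP with ReLU."""

    def __init__(self, d_model: int, d_ff: int, dropout: float, rng: np.random.Generator):
        super().__init__()
        self.lin1 = self.add_child("lin1", Dense(d_model, d_ff, rng))
        self.lin2 = self.add_child("lin2", Dense(d_ff, d_model, rng))
        self.dropout = self.add_child("dropout", Dropout(dropout))
        self._relu_mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, rng, train: bool) -> np.ndarray:
        h = self.lin1.forward(x)
        self._relu_mask = h > 0
        h = h * self._relu_mask
        h = self.dropout.forward(h, rng, train)
        return self.lin2.forward(h)

    def backward(self, g: np.ndarray) -> np.ndarray:
        g = self.lin2.backward(g)
        g = self.dropout.backward(g)
        g = g * self._relu_mask
        return self.lin1.backward(g)


class EncoderLayer(Layer):
    """Post-norm transformer encoder layer: self-attention then feed-forward."""

    def __init__(self, d_model: int, n_heads: int, d_ff: int, dropout: float, rng):
        super().__init__()
        self.self_attn = self.add_child("self_attn", MultiHeadAttention(d_model, n_heads, dropout, rng))
        self.ff = self.add_child("ff", FeedForward(d_model, d_ff, dropout, rng))
        self.norm1 = self.add_child("norm1", LayerNorm(d_model))
        self.norm2 = self.add_child("norm2", LayerNorm(d_model))
        self.drop1 = self.add_child("drop1", Dropout(dropout))
        self.drop2 = self.add_child("drop2", Dropout(dropout))

    def forward(self, x, src_mask, rng, train):
        a = self.self_attn.forward(x, x, x, src_mask, rng, train)
        x = self.norm1.forward(x + self.drop1.forward(a, rng, train))
        f = self.ff.forward(x, rng, train)
        return self.norm2.forward(x + self.drop2.forward(f, rng, train))

    def backward(self, g):
        g = self.norm2.backward(g)
        g_ff = self.ff.backward(self.drop2.backward(g))
        g = g + g_ff
        g = self.norm1.backward(g)
        dq, dk, dv = self.self_attn.backward(self.drop1.backward(g))
        return g + dq + dk + dv


class DecoderLayer(Layer):
    """Post-norm decoder layer: causal self-attention, cross-attention, feed-forward."""

    def __init__(self, d_model: int, n_heads: int, d_ff: int, dropout: float, rng):
        super().__init__()
        self.self_attn = self.add_child("self_attn", MultiHeadAttention(d_model, n_heads, dropout, rng))
        self.cross_attn = self.add_child("cross_attn", MultiHeadAttention(d_model, n_heads, dropout, rng))
        self.ff = self.add_child("ff", FeedForward(d_model, d_ff, dropout, rng))
        self.norm1 = self.add_child("norm1", LayerNorm(d_model))
        self.norm2 = self.add_child("norm2", LayerNorm(d_model))
        self.norm3 = self.add_child("norm3", LayerNorm(d_model))
        self.drop1 = self.add_child("drop1", Dropout(dropout))
        self.drop2 = self.add_child("drop2", Dropout(dropout))
        self.drop3 = self.add_child("drop3", Dropout(dropout))

    def forward(self, x, memory, tgt_mask, memory_mask, rng, train):
        a = self.self_attn.forward(x, x, x, tgt_mask, rng, train)
        x = self.norm1.forward(x + self.drop1.forward(a, rng, train))
        c = self.cross_attn.forward(x, memory, memory, memory_mask, rng, train)
        x = self.norm2.forward(x + self.drop2.forward(c, rng, train))
        f = self.ff.forward(x, rng, train)
        return self.norm3.forward(x + self.drop3.forward(f, rng, train))

    def backward(self, g):
        g = self.norm3.backward(g)
        g = g + self.ff.backward(self.drop3.backward(g))
        g = self.norm2.backward(g)
        dq, dk, dv = self.cross_attn.backward(self.drop2.backward(g))
        d_memory = dk + dv
        g = g + dq
        g = self.norm1.backward(g)
        dq, dk, dv = self.self_attn.backward(self.drop1.backward(g))
        return g + dq + dk + dv, d_memory


class Adam:
    """Adam optimizer with optional decoupled-style L2 weight decay added to the gradient."""

    def __init__(
        self,
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.98),
        eps: float = 1e-9,
        weight_decay: float = 0.0,
    ):
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self, named_params: Iterator[tuple[str, np.ndarray, np.ndarray]]):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for name, param, grad in named_params:
            g = grad
            if self.weight_decay:
                g = g + self.weight_decay * param
            if name not in self._m:
                self._m[name] = np.zeros_like(param)
                self._v[name] = np.zeros_like(param)
            m, v = self._m[name], self._v[name]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            param -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def causal_mask(length: int) -> np.ndarray:
    """Additive mask forbidding attention to future positions; shape (1,1,L,L)."""
    mask = np.triu(np.full((length, length), NEG_INF), k=1)
    return mask[None, None, :, :]


def padding_mask(pad: np.ndarray) -> np.ndarray:
    """Additive key-padding mask from a boolean (batch, L) 'is-pad' array."""
    return np.where(pad[:, None, None, :], NEG_INF, 0.0)
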