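"""Transformer building blocks on top of the autograd engine.

Conventions: inputs are (batch, positions, width) tensors; attention masks are
*additive* numpy arrays (0 where attention is allowed, a large negative number
where it is forbidden) so they combine by summation and stay constants on the
tape.  Layer arrangement is post-norm by default (``LayerNorm(x + sublayer(x))``)
with a pre-norm option.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, gelu, layer_norm, softmax

NEG_INF = -1e9


class Module:
    """Base class providing recursive parameter discovery."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        scale = np.sqrt(6.0 / (d_in + d_out))
        self.weight = Tensor(rng.uniform(-scale, scale, size=(d_in, d_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    def __init__(self, d: int):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta)


class MultiHeadAttention(Module):
    """Scaled dot-product attention with `n_heads` heads.

    ``__call__`` returns (output, probs) where probs is the detached
    (batch, heads, queries, keys) attention array — the raw material for
    rollout attribution.
    """

    def __init__(self, d: int, n_heads: int, rng: np.random.Generator):
        if d % n_heads:
            raise ValueError(f"width {d} not divisible by {n_heads} heads")
        self.n_heads = n_heads
        self.d_head = d // n_heads
        self.w_q = Linear(d, d, rng)
        self.w_k = Linear(d, d, rng)
        self.w_v = Linear(d, d, rng)
        self.w_o = Linear(d, d, rng)

    def _split(self, x: Tensor) -> Tensor:
        b, t, d = x.shape
        return x.reshape(b, t, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def __call__(
        self,
        query: Tensor,
        key: Tensor,
        value: Tensor,
        additive_mask: np.ndarray | None = None,
    ) -> tuple[Tensor, np.ndarray]:
        b, tq, _ = query.shape
        q = self._split(self.w_q(query))
        k = self._split(self.w_k(key))
        v = self._split(self.w_v(value))
        scores = q @ k.transpose(0, 1, 3, 2) * (1.0 / np.sqrt(self.d_head))
        if additive_mask is not None:
            scores = scores + additive_mask
        probs = softmax(scores, axis=-1)
        out = probs @ v
        out = out.transpose(0, 2, 1, 3).reshape(b, tq, self.n_heads * self.d_head)
        return self.w_o(out), probs.data.copy()


class FeedForward(Module):
    def __init__(self, d: int, d_ff: int, rng: np.random.Generator):
        self.lin1 = Linear(d, d_ff, rng)
        self.lin2 = Linear(d_ff, d, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.lin2(gelu(self.lin1(x)))


class EncoderLayer(Module):
    """Self-attention + feed-forward with residuals and layer norm."""

    def __init__(self, d: int, n_heads: int, d_ff: int, rng: np.random.Generator, pre_norm: bool = False):
        self.attn = MultiHeadAttention(d, n_heads, rng)
        self.ffn = FeedForward(d, d_ff, rng)
        self.norm1 = LayerNorm(d)
        self.norm2 = LayerNorm(d)
        self.pre_norm = pre_norm

    def __call__(self, x: Tensor, additive_mask: np.ndarray | None = None) -> Tensor:
        if self.pre_norm:
            a, _ = self.attn(self.norm1(x), self.norm1(x), self.norm1(x), additive_mask)
            x = x + a
            x = x + self.ffn(self.norm2(x))
            return x
        a, _ = self.attn(x, x, x, additive_mask)
        x = self.norm1(x + a)
        x = self.norm2(x + self.ffn(x))
        return x


class DecoderLayer(Module):
    """Causal self-attention over terms, cross-attention to residues, FFN."""

    def __init__(self, d: int, n_heads: int, d_ff: int, rng: np.random.Generator, pre_norm: bool = False):
        self.self_attn = MultiHeadAttention(d, n_heads, rng)
        self.cross_attn = MultiHeadAttention(d, n_heads, rng)
        self.ffn = FeedForward(d, d_ff, rng)
        self.norm1 = LayerNorm(d)
        self.norm2 = LayerNorm(d)
        self.norm3 = LayerNorm(d)
        self.pre_norm = pre_norm

    def __call__(
        self,
        x: Tensor,
        memory: Tensor,
        self_mask: np.ndarray | None,
        cross_mask: np.ndarray | None,
    ) -> tuple[Tensor, np.ndarray]:
        if self.pre_norm:
            a, _ = self.self_attn(self.norm1(x), self.norm1(x), self.norm1(x), self_mask)
            x = x + a
            c, cross_probs = self.cross_attn(self.norm2(x), memory, memory, cross_mask)
            x = x + c
            x = x + self.ffn(self.norm3(x))
            return x, cross_probs
        a, _ = self.self_attn(x, x, x, self_mask)
        x = self.norm1(x + a)
        c, cross_probs = self.cross_attn(x, memory, memory, cross_mask)
        x = self.norm2(x + c)
        x = self.norm3(x + self.ffn(x))
        return x, cross_probs
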