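"""Transformer-style attention pooling.

A learnable context token is prepended to the sequence of frame
encodings; after N self-attention encoder layers the output at the token
position summarises the sequence. Matches the post-layer-norm encoder
layout (attention sublayer, then position-wise feed-forward, each with a
residual connection and layer normalisation).
"""

from __future__ import annotations

import numpy as np

from .core import Layer, Param
from .layers import Dense, ReLU

__all__ = ["LayerNorm", "MultiHeadSelfAttention", "TransformerEncoderLayer",
           "AttentionPool"]


class LayerNorm(Layer):
    def __init__(self, dim: int, eps: float = 1e-5, dtype=np.float32) -> None:
        self.gamma = Param(np.ones(dim, dtype=dtype), name="ln_gamma")
        self.beta = Param(np.zeros(dim, dtype=dtype), name="ln_beta")
        self.eps = eps
        self._cache: list[tuple] = []

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mean = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        y = self.gamma.data * xhat + self.beta.data
        if train:
            self._cache.append((xhat, inv))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache.pop()
        d = dy.shape[-1]
        self.gamma.grad += (dy * xhat).reshape(-1, d).sum(axis=0)
        self.beta.grad += dy.reshape(-1, d).sum(axis=0)
        dxhat = dy * self.gamma.data
        dx = inv / d * (
            d * dxhat
            - dxhat.sum(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=-1, keepdims=True)
        )
        return dx


class MultiHeadSelfAttention(Layer):
    def __init__(self, d_model: int, n_heads: int,
                 rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        if d_model % n_heads:
            raise ValueError(f"d_model={d_model} not divisible by n_heads={n_heads}")
        rng = rng or np.random.default_rng()
        self.d_model = d_model
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = Dense(d_model, d_model, rng=rng, dtype=dtype)
        self.wk = Dense(d_model, d_model, rng=rng, dtype=dtype)
        self.wv = Dense(d_model, d_model, rng=rng, dtype=dtype)
        self.wo = Dense(d_model, d_model, rng=rng, dtype=dtype)
        self._cache: list[tuple] = []

    def params(self) -> list[Param]:
        return (self.wq.params() + self.wk.params() + self.wv.params()
                + self.wo.params())

    def _split(self, x: np.ndarray) -> np.ndarray:
        b, t, _ = x.shape
        return x.reshape(b, t, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        b, h, t, dk = x.shape
        return x.transpose(0, 2, 1, 3).reshape(b, t, h * dk)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        q = self._split(self.wq.forward(x, train))
        k = self._split(self.wk.forward(x, train))
        v = self._split(self.wv.forward(x, train))
        scale = 1.0 / np.sqrt(self.d_head)
        scores = np.einsum("bhtd,bhsd->bhts", q, k, optimize=True) * scale
        scores -= scores.max(axis=-1, keepdims=True)
        attn = np.exp(scores)
        attn /= attn.sum(axis=-1, keepdims=True)
        ctx = np.einsum("bhts,bhsd->bhtd", attn, v, optimize=True)
        out = self.wo.forward(self._merge(ctx), train)
        if train:
            self._cache.append((q, k, v, attn))
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        q, k, v, attn = self._cache.pop()
        scale = 1.0 / np.sqrt(self.d_head)
        dctx = self._split(self.wo.backward(dy))
        dattn = np.einsum("bhtd,bhsd->bhts", dctx, v, optimize=True)
        dv = np.einsum("bhts,bhtd->bhsd", attn, dctx, optimize=True)
        # softmax backward over the key axis
        dscores = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
        dq = np.einsum("bhts,bhsd->bhtd", dscores, k, optimize=True) * scale
        dk = np.einsum("bhts,bhtd->bhsd", dscores, q, optimize=True) * scale
        dx = self.wq.backward(self._merge(dq))
        dx = dx + self.wk.backward(self._merge(dk))
        dx = dx + self.wv.backward(self._merge(dv))
        return dx


class TransformerEncoderLayer(Layer):
    """Self-attention + feed-forward, each with residual and layer norm."""

    def __init__(self, d_model: int, n_heads: int, d_ff: int,
                 rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        rng = rng or np.random.default_rng()
        self.attn = MultiHeadSelfAttention(d_model, n_heads, rng=rng, dtype=dtype)
        self.ln1 = LayerNorm(d_model, dtype=dtype)
        self.ff1 = Dense(d_model, d_ff, rng=rng, dtype=dtype)
        self.act = ReLU()
        self.ff2 = Dense(d_ff, d_model, rng=rng, dtype=dtype)
        self.ln2 = LayerNorm(d_model, dtype=dtype)

    def params(self) -> list[Param]:
        return (self.attn.params() + self.ln1.params() + self.ff1.params()
                + self.ff2.params() + self.ln2.params())

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h = self.ln1.forward(x + self.attn.forward(x, train), train)
        f = self.ff2.forward(self.act.forward(self.ff1.forward(h, train), train), train)
        return self.ln2.forward(h + f, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = self.ln2.backward(dy)
        df = self.ff1.backward(self.act.backward(self.ff2.backward(dh)))
        dh = dh + df
        dx = self.ln1.backward(dh)
        return dx + self.attn.backward(dx)


class AttentionPool(Layer):
    """Pool a sequence of encodings into one context vector.

    Positional embeddings are learned and added to the whole sequence
    (context token at position 0); ``use_positional=False`` makes the
    pooling permutation-invariant in the context frames.
    """

    def __init__(self, d_model: int, n_heads: int = 8, n_layers: int = 3,
                 d_ff: int | None = None, max_len: int = 64,
                 use_positional: bool = True,
                 rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        rng = rng or np.random.default_rng()
        d_ff = 2 * d_model if d_ff is None else d_ff
        self.d_model = d_model
        self.use_positional = use_positional
        self.c0 = Param((rng.standard_normal(d_model) * 0.02).astype(dtype), name="c0")
        self.pos = Param((rng.standard_normal((max_len + 1, d_model)) * 0.02).astype(dtype),
                         name="pos_emb")
        self.layers = [TransformerEncoderLayer(d_model, n_heads, d_ff, rng=rng, dtype=dtype)
                       for _ in range(n_layers)]
        self._cache: list[int] = []

    def params(self) -> list[Param]:
        out = [self.c0]
        if self.use_positional:
            out.append(self.pos)
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.ndim != 3 or x.shape[1] < 1:
            raise ValueError("expected non-empty (batch, frames, d_model) input")
        if x.shape[2] != self.d_model:
            raise ValueError(f"encoding size {x.shape[2]} != d_model {self.d_model}")
        b, t, _ = x.shape
        if t + 1 > self.pos.data.shape[0]:
            raise ValueError(f"context of {t} frames exceeds max_len")
        seq = np.concatenate([np.broadcast_to(self.c0.data, (b, 1, self.d_model)), x],
                             axis=1)
        if self.use_positional:
            seq = seq + self.pos.data[None, : t + 1, :]
        else:
            seq = seq.copy()
        for layer in self.layers:
            seq = layer.forward(seq, train=train)
        if train:
            self._cache.append(t)
        return seq[:, 0, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        t = self._cache.pop()
        b = dy.shape[0]
        dseq = np.zeros((b, t + 1, self.d_model), dtype=dy.dtype)
        dseq[:, 0, :] = dy
        for layer in reversed(self.layers):
            dseq = layer.backward(dseq)
        if self.use_positional:
            self.pos.grad[: t + 1] += dseq.sum(axis=0)
        self.c0.grad += dseq[:, 0, :].sum(axis=0)
        return dseq[:, 1:, :]
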