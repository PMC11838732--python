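"""Neural building blocks: Linear, LayerNorm, Embedding, multi-head
self-attention and pre-norm transformer blocks with optional attention bias.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor


class Module:
    def parameters(self):
        out = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append(item)
        return out

    def n_parameters(self):
        return sum(p.data.size for p in self.parameters())

    def state_arrays(self):
        return [p.data for p in self.parameters()]


def _init(rng, *shape, scale=0.02):
    return Tensor(rng.normal(0.0, scale, size=shape).astype(np.float32),
                  requires_grad=True)


class Linear(Module):
    def __init__(self, rng, d_in, d_out, bias=True):
        self.w = _init(rng, d_in, d_out, scale=1.0 / np.sqrt(d_in))
        self.b = Tensor(np.zeros(d_out, dtype=np.float32), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.w
        if self.b is not None:
            y = y + self.b
        return y


class MLP(Module):
    """Stack of Linear layers with ReLU between (not after) them."""

    def __init__(self, rng, dims, bias=True):
        self.layers = [Linear(rng, a, b, bias=bias) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu()
        return x


class LayerNorm(Module):
    def __init__(self, dim, eps=1e-5):
        self.gain = Tensor(np.ones(dim, dtype=np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(dim, dtype=np.float32), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gain + self.bias


class Embedding(Module):
    def __init__(self, rng, n, dim):
        self.table = _init(rng, n, dim)

    def __call__(self, indices: np.ndarray) -> Tensor:
        return self.table.take_rows(indices)


class SelfAttention(Module):
    def __init__(self, rng, width, heads, head_dim=None, causal=False):
        self.heads = heads
        self.head_dim = head_dim or width // heads
        inner = self.heads * self.head_dim
        self.wq = Linear(rng, width, inner)
        self.wk = Linear(rng, width, inner)
        self.wv = Linear(rng, width, inner)
        self.wo = Linear(rng, inner, width)
        self.causal = causal

    def __call__(self, x: Tensor, attn_bias: np.ndarray | None = None) -> Tensor:
        B, T, _ = x.shape
        H, Dh = self.heads, self.head_dim

        def split(t):
            return t.reshape(B, T, H, Dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        logits = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(Dh))
        bias = None
        if attn_bias is not None:
            bias = attn_bias  # (B, 1, 1, T) or (B, 1, T, T)
        if self.causal:
            causal_bias = np.triu(np.full((T, T), -1e9, dtype=np.float32), k=1)
            bias = causal_bias if bias is None else bias + causal_bias
        if bias is not None:
            logits = logits + Tensor(bias)
        att = logits.softmax(axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(B, T, H * Dh)
        return self.wo(out)


class TransformerBlock(Module):
    """Pre-norm transformer block, MLP ratio 4, GELU."""

    def __init__(self, rng, width, heads, head_dim=None, mlp_ratio=4, causal=False):
        self.ln1 = LayerNorm(width)
        self.attn = SelfAttention(rng, width, heads, head_dim, causal=causal)
        self.ln2 = LayerNorm(width)
        hidden = width * mlp_ratio
        self.fc1 = Linear(rng, width, hidden)
        self.fc2 = Linear(rng, hidden, width)

    def __call__(self, x: Tensor, attn_bias=None) -> Tensor:
        x = x + self.attn(self.ln1(x), attn_bias)
        return x + self.fc2(self.fc1(self.ln2(x)).gelu())


class Transformer(Module):
    def __init__(self, rng, width, layers, heads, head_dim=None, mlp_ratio=4,
                 causal=False):
        self.blocks = [TransformerBlock(rng, width, heads, head_dim, mlp_ratio,
                                        causal=causal) for _ in range(layers)]
        self.ln_f = LayerNorm(width)

    def __call__(self, x: Tensor, attn_bias=None) -> Tensor:
        for blk in self.blocks:
            x = blk(x, attn_bias)
        return self.ln_f(x)


def padding_attn_bias(valid: np.ndarray) -> np.ndarray:
    """(B, T) boolean validity -> (B, 1, 1, T) additive bias masking padding."""
    bias = np.where(valid[:, None, None, :], 0.0, -1e9).astype(np.float32)
    return bias
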