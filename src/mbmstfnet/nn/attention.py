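"""Multi-head scaled dot-product self-attention (bias-free projections).

Queries, keys and values are all the same input sequence.  The fused
query/key/value projections are single ``d_model x d_model`` matrices whose
outputs are viewed as ``n_heads`` blocks of width ``d_k = d_model /
n_heads``; scores are ``q k^T / sqrt(d_k)``, softmax-normalised over the
key axis, applied to the values, and the concatenated heads are projected
by an output matrix.  None of the four projections carries a bias.
"""

from __future__ import annotations

import numpy as np

from .layers import Module, Parameter, _glorot, softmax

__all__ = ["MultiHeadAttention"]


class MultiHeadAttention(Module):
    def __init__(self, d_model: int, n_heads: int, rng=None, dtype=np.float32):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        rng = rng or np.random.default_rng(0)
        self.d_model, self.n_heads = d_model, n_heads
        self.d_k = d_model // n_heads
        self.Wq = Parameter(_glorot(rng, (d_model, d_model), dtype), "Wq")
        self.Wk = Parameter(_glorot(rng, (d_model, d_model), dtype), "Wk")
        self.Wv = Parameter(_glorot(rng, (d_model, d_model), dtype), "Wv")
        self.Wo = Parameter(_glorot(rng, (d_model, d_model), dtype), "Wo")
        self._cache = None
        self.last_weights: np.ndarray | None = None  # (B, heads, T, T)

    def _split(self, x):
        B, T, _ = x.shape
        return x.reshape(B, T, self.n_heads, self.d_k).transpose(0, 2, 1, 3)

    def _merge(self, x):
        B, h, T, dk = x.shape
        return np.ascontiguousarray(x.transpose(0, 2, 1, 3)).reshape(B, T, h * dk)

    def forward(self, x: np.ndarray) -> np.ndarray:
        q = self._split(x @ self.Wq.value)
        k = self._split(x @ self.Wk.value)
        v = self._split(x @ self.Wv.value)
        scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(self.d_k)
        attn = softmax(scores, axis=-1)
        ctx = attn @ v
        merged = self._merge(ctx)
        out = merged @ self.Wo.value
        self._cache = (x, q, k, v, attn, merged)
        self.last_weights = attn
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, q, k, v, attn, merged = self._cache
        B, T, D = x.shape
        x2 = x.reshape(-1, D)
        self.Wo.grad += merged.reshape(-1, D).T @ dout.reshape(-1, D)
        dmerged = dout @ self.Wo.value.T
        dctx = self._split(dmerged)
        dattn = dctx @ v.transpose(0, 1, 3, 2)
        dv = attn.transpose(0, 1, 3, 2) @ dctx
        # softmax backward over the key axis
        dscores = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
        dscores /= np.sqrt(self.d_k)
        dq = dscores @ k
        dk_ = dscores.transpose(0, 1, 3, 2) @ q
        dq_full = self._merge(dq).reshape(-1, D)
        dk_full = self._merge(dk_).reshape(-1, D)
        dv_full = self._merge(dv).reshape(-1, D)
        self.Wq.grad += x2.T @ dq_full
        self.Wk.grad += x2.T @ dk_full
        self.Wv.grad += x2.T @ dv_full
        dx = (dq_full @ self.Wq.value.T + dk_full @ self.Wk.value.T
              + dv_full @ self.Wv.value.T)
        return dx.reshape(B, T, D)
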