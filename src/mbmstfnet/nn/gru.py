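"""Gated recurrent units with truncated-free (full) backprop through time.

Gate equations, with sigma the logistic function and ``o`` elementwise
product:

    z_t = sigma(W_z x_t + U_z h_{t-1} + b_z)
    r_t = sigma(W_r x_t + U_r h_{t-1} + b_r)
    g_t = tanh(W_h x_t + r_t o (U_h h_{t-1}) + b_h)
    h_t = (1 - z_t) o h_{t-1} + z_t o g_t

Each gate has a single bias vector.  A bidirectional layer runs one GRU in
chronological and one in reversed order and concatenates the per-step
hidden states.
"""

from __future__ import annotations

import numpy as np

from .layers import Module, Parameter, _glorot

__all__ = ["gru_cell_step", "GRU", "BiGRU"]


def _sigmoid(x):
    # evaluated on the negative half-line to avoid exp overflow
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def gru_cell_step(x_t, h_prev, W, U, b):
    """One GRU step on stacked gate matrices.

    ``W`` is ``(3H, D)``, ``U`` is ``(3H, H)``, ``b`` is ``(3H,)``; the row
    blocks are ordered update, reset, candidate.
    """
    if not (np.all(np.isfinite(x_t)) and np.all(np.isfinite(h_prev))):
        raise FloatingPointError("non-finite input to GRU step")
    H = h_prev.shape[-1]
    gx = x_t @ W.T + b
    gh = h_prev @ U.T
    z = _sigmoid(gx[..., :H] + gh[..., :H])
    r = _sigmoid(gx[..., H:2 * H] + gh[..., H:2 * H])
    g = np.tanh(gx[..., 2 * H:] + r * gh[..., 2 * H:])
    return (1.0 - z) * h_prev + z * g


class GRU(Module):
    """Single-direction GRU over a ``(B, T, D)`` sequence."""

    def __init__(self, in_dim: int, hidden: int, reverse: bool = False,
                 rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.in_dim, self.hidden, self.reverse = in_dim, hidden, reverse
        self.W = Parameter(_glorot(rng, (3 * hidden, in_dim), dtype), "W")
        self.U = Parameter(_glorot(rng, (3 * hidden, hidden), dtype), "U")
        self.b = Parameter(np.zeros(3 * hidden, dtype=dtype), "b")
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, D = x.shape
        H = self.hidden
        order = range(T - 1, -1, -1) if self.reverse else range(T)
        h = np.zeros((B, H), dtype=x.dtype)
        outs = np.empty((B, T, H), dtype=x.dtype)
        steps = []
        U, b = self.U.value, self.b.value
        # the input projection does not depend on the recurrence: one GEMM
        gx_all = x.reshape(B * T, D) @ self.W.value.T
        gx_all = gx_all.reshape(B, T, 3 * H) + b
        for t in order:
            gx = gx_all[:, t]
            gh = h @ U.T
            z = _sigmoid(gx[:, :H] + gh[:, :H])
            r = _sigmoid(gx[:, H:2 * H] + gh[:, H:2 * H])
            uh = gh[:, 2 * H:]
            g = np.tanh(gx[:, 2 * H:] + r * uh)
            h_new = (1.0 - z) * h + z * g
            steps.append((t, h, z, r, g, uh))
            h = h_new
            outs[:, t] = h
        self._cache = (steps, x)
        return outs

    def backward(self, dout: np.ndarray) -> np.ndarray:
        steps, x = self._cache
        B, T, D = x.shape
        H = self.hidden
        W, U = self.W.value, self.U.value
        da_all = np.empty((B, T, 3 * H), dtype=dout.dtype)
        dh_next = np.zeros((B, H), dtype=dout.dtype)
        for t, h_prev, z, r, g, uh in reversed(steps):
            dh = dout[:, t] + dh_next
            dg = dh * z * (1.0 - g * g)
            dz = dh * (g - h_prev) * z * (1.0 - z)
            dh_prev = dh * (1.0 - z)
            dr = dg * uh * r * (1.0 - r)
            duh = dg * r
            da_all[:, t, :H] = dz
            da_all[:, t, H:2 * H] = dr
            da_all[:, t, 2 * H:] = dg
            dgh = np.concatenate([dz, dr, duh], axis=1)
            self.U.grad += dgh.T @ h_prev
            dh_next = dh_prev + dgh @ U
        da2 = da_all.reshape(B * T, 3 * H)
        self.W.grad += da2.T @ x.reshape(B * T, D)
        self.b.grad += da2.sum(axis=0)
        return (da2 @ W).reshape(B, T, D)


class BiGRU(Module):
    """Bidirectional GRU: concatenated forward and backward hidden states."""

    def __init__(self, in_dim: int, hidden: int, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.fwd = GRU(in_dim, hidden, reverse=False, rng=rng, dtype=dtype)
        self.bwd = GRU(in_dim, hidden, reverse=True, rng=rng, dtype=dtype)
        self.hidden = hidden

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.concatenate([self.fwd.forward(x), self.bwd.forward(x)],
                              axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        H = self.hidden
        return (self.fwd.backward(dout[..., :H])
                + self.bwd.backward(dout[..., H:]))
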