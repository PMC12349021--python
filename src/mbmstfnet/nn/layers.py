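"""Dense, convolutional and pooling layers with explicit backprop."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Parameter", "Module", "Conv2d", "Linear", "ReLU", "MaxPool2d",
           "softmax", "softmax_cross_entropy"]


class Parameter:
    """A trainable array and its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Module:
    """Base class: parameter bookkeeping shared by all layers."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for attr in vars(self).values():
            if isinstance(attr, Parameter):
                params.append(attr)
            elif isinstance(attr, Module):
                params.extend(attr.parameters())
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0


def _glorot(rng, shape, dtype):
    fan_in, fan_out = shape[-1], shape[-2] if len(shape) > 1 else shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _he(rng, shape, fan_in, dtype):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv2d(Module):
    """Stride-1 2-D convolution with symmetric zero padding (im2col + GEMM)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, pad: int | None = None,
                 bias: bool = True, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        if pad is None:
            pad = kernel // 2  # same-padding for odd kernels
        self.in_ch, self.out_ch, self.kernel, self.pad = in_ch, out_ch, kernel, pad
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(_he(rng, (out_ch, in_ch, kernel, kernel),
                                    fan_in, dtype), "weight")
        self.bias = Parameter(np.zeros(out_ch, dtype=dtype), "bias") if bias else None
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        if C != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {C}")
        k, p = self.kernel, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))
        Ho, Wo = win.shape[2], win.shape[3]
        cols = np.ascontiguousarray(
            win.transpose(0, 2, 3, 1, 4, 5)).reshape(B * Ho * Wo, C * k * k)
        wmat = self.weight.value.reshape(self.out_ch, -1)
        out = cols @ wmat.T
        if self.bias is not None:
            out += self.bias.value
        self._cache = (cols, (B, C, H, W), Ho, Wo)
        return out.reshape(B, Ho, Wo, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray,
                 need_input_grad: bool = True) -> np.ndarray | None:
        cols, xshape, Ho, Wo = self._cache
        B, C, H, W = xshape
        k, p = self.kernel, self.pad
        dflat = np.ascontiguousarray(
            dout.transpose(0, 2, 3, 1)).reshape(-1, self.out_ch)
        self.weight.grad += (dflat.T @ cols).reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += dflat.sum(axis=0)
        if not need_input_grad:
            return None
        dcols = dflat @ self.weight.value.reshape(self.out_ch, -1)
        dcols = dcols.reshape(B, Ho, Wo, C, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=dout.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + Ho, j:j + Wo] += dcols[:, :, :, :, i, j]
        return dxp[:, :, p:p + H, p:p + W]


class Linear(Module):
    """Affine map on the last axis."""

    def __init__(self, in_dim: int, out_dim: int, bias: bool = True,
                 rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.in_dim, self.out_dim = in_dim, out_dim
        self.weight = Parameter(_glorot(rng, (out_dim, in_dim), dtype), "weight")
        self.bias = Parameter(np.zeros(out_dim, dtype=dtype), "bias") if bias else None
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = x @ self.weight.value.T
        if self.bias is not None:
            out += self.bias.value
        self._cache = x
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        x2 = x.reshape(-1, self.in_dim)
        d2 = dout.reshape(-1, self.out_dim)
        self.weight.grad += d2.T @ x2
        if self.bias is not None:
            self.bias.grad += d2.sum(axis=0)
        return (d2 @ self.weight.value).reshape(x.shape)


class ReLU(Module):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2d(Module):
    """Max pooling with kernel/stride/padding (padding uses -inf)."""

    def __init__(self, kernel: int, stride: int | None = None, pad: int = 0):
        self.kernel = kernel
        self.stride = stride if stride is not None else kernel
        self.pad = pad
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        k, s, p = self.kernel, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)),
                    constant_values=-np.inf)
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        Ho, Wo = win.shape[2], win.shape[3]
        flat = win.reshape(B, C, Ho, Wo, k * k)
        arg = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, arg[..., np.newaxis], axis=-1)[..., 0]
        self._cache = (arg, (B, C, H, W), Ho, Wo)
        return np.ascontiguousarray(out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        arg, (B, C, H, W), Ho, Wo = self._cache
        k, s, p = self.kernel, self.stride, self.pad
        if s == k and p == 0:
            # non-overlapping windows: scatter without index arithmetic
            win = np.zeros((B, C, Ho, Wo, k * k), dtype=dout.dtype)
            np.put_along_axis(win, arg[..., np.newaxis],
                              dout[..., np.newaxis], axis=-1)
            back = win.reshape(B, C, Ho, Wo, k, k).transpose(0, 1, 2, 4, 3, 5)
            out = np.zeros((B, C, H, W), dtype=dout.dtype)
            out[:, :, :Ho * k, :Wo * k] = back.reshape(B, C, Ho * k, Wo * k)
            return out
        dxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=dout.dtype)
        ai, aj = np.divmod(arg, k)
        oi = np.arange(Ho)[:, np.newaxis] * s
        oj = np.arange(Wo)[np.newaxis, :] * s
        rows = (ai + oi).reshape(B, C, -1)
        cols = (aj + oj).reshape(B, C, -1)
        bidx = np.arange(B)[:, np.newaxis, np.newaxis]
        cidx = np.arange(C)[np.newaxis, :, np.newaxis]
        np.add.at(dxp, (bidx, cidx, rows, cols), dout.reshape(B, C, -1))
        return dxp[:, :, p:p + H, p:p + W]


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    shifted = x - x.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    probs = softmax(logits.astype(np.float64), axis=-1)
    n = logits.shape[0]
    eps = 1e-12
    loss = -float(np.mean(np.log(probs[np.arange(n), labels] + eps)))
    dlogits = probs
    dlogits[np.arange(n), labels] -= 1.0
    return loss, (dlogits / n).astype(logits.dtype)
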