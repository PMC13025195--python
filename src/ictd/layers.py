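"""Neural-network building blocks over the numpy autodiff core.

Layers keep their parameters as ``Tensor``s with ``requires_grad=True`` and
are initialised from an explicit :class:`numpy.random.Generator`, so a model
built twice from the same seed is parameter-identical.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autodiff import Tensor, _make, concat

__all__ = [
    "Module", "Linear", "Conv1d", "DepthwiseConv1d", "LayerNorm",
    "Dropout", "MultiHeadSelfAttention", "Adam", "cross_entropy",
    "conv1d", "depthwise_conv1d",
]


# ----------------------------------------------------------------------
# functional convolutions (same padding, odd kernels)

def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None,
           mask: np.ndarray | None = None) -> Tensor:
    """1-D convolution over (n, C, T) with same padding.

    When `mask` (n, T boolean) is given, invalid samples are zeroed and each
    output is renormalised by k/(number of valid inputs under the kernel);
    positions with no valid input are zero. This is the "effective region"
    convolution used by the partial-convolution path.
    """
    n, C, T = x.shape
    O, Ci, k = w.shape
    if Ci != C:
        raise ValueError(f"conv1d: input has {C} channels, kernel expects {Ci}")
    if k % 2 == 0:
        raise ValueError("conv1d supports odd kernels only")
    if k > 2 * T - 1:
        # with zero same-padding, taps beyond the sequence only ever see
        # zeros, so the centered 2T-1 sub-kernel computes the identical map
        c = (k - (2 * T - 1)) // 2
        w = w[:, :, c:k - c]
        k = 2 * T - 1
    p = k // 2
    xd = x.data
    scale = None
    if mask is not None:
        # renormalise by valid/in-bounds taps so boundary padding (which is
        # zero anyway) does not inflate outputs; positions with no valid
        # input under the kernel are zeroed
        m = np.asarray(mask, dtype=np.float64)
        xd = xd * m[:, None, :]
        mp = np.pad(m, ((0, 0), (p, p)))
        ones = np.pad(np.ones_like(m), ((0, 0), (p, p)))
        counts = np.zeros((n, T))
        inbounds = np.zeros((n, T))
        for j in range(k):
            counts += mp[:, j:j + T]
            inbounds += ones[:, j:j + T]
        with np.errstate(divide="ignore"):
            scale = np.where(counts > 0, inbounds / np.maximum(counts, 1), 0.0)
    xp = np.pad(xd, ((0, 0), (0, 0), (p, p)))
    y = np.zeros((n, O, T))
    for j in range(k):
        y += np.einsum("nct,oc->not", xp[:, :, j:j + T], w.data[:, :, j])
    if scale is not None:
        y *= scale[:, None, :]
    if b is not None:
        yb = y + b.data[None, :, None]
        if scale is not None:
            yb = np.where(scale[:, None, :] > 0, yb, 0.0)
        y = yb
    parents = (x, w) if b is None else (x, w, b)
    out = _make(y, parents)
    if out.requires_grad:
        def bw():
            g = out.grad
            if scale is not None:
                g = g * scale[:, None, :]
            if b is not None and b.requires_grad:
                gb = out.grad if scale is None else np.where(
                    scale[:, None, :] > 0, out.grad, 0.0)
                b._accum(gb.sum(axis=(0, 2)))
            if w.requires_grad:
                gw = np.zeros_like(w.data)
                for j in range(k):
                    gw[:, :, j] = np.einsum("not,nct->oc", g, xp[:, :, j:j + T])
                w._accum(gw)
            if x.requires_grad:
                gxp = np.zeros_like(xp)
                for j in range(k):
                    gxp[:, :, j:j + T] += np.einsum("not,oc->nct", g, w.data[:, :, j])
                gx = gxp[:, :, p:p + T]
                if mask is not None:
                    gx = gx * np.asarray(mask, dtype=np.float64)[:, None, :]
                x._accum(gx)
        out._backward = bw
    return out


def depthwise_conv1d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Per-channel (depthwise) convolution; kernel w has shape (C, k)."""
    n, C, T = x.shape
    Cw, k = w.shape
    if Cw != C:
        raise ValueError(f"depthwise_conv1d: {C} channels vs kernel {Cw}")
    if k % 2 == 0:
        raise ValueError("depthwise_conv1d supports odd kernels only")
    if k > 2 * T - 1:
        c = (k - (2 * T - 1)) // 2
        w = w[:, c:k - c]
        k = 2 * T - 1
    p = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p)))
    y = np.zeros((n, C, T))
    for j in range(k):
        y += xp[:, :, j:j + T] * w.data[None, :, j, None]
    if b is not None:
        y += b.data[None, :, None]
    parents = (x, w) if b is None else (x, w, b)
    out = _make(y, parents)
    if out.requires_grad:
        def bw():
            g = out.grad
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 2)))
            if w.requires_grad:
                gw = np.zeros_like(w.data)
                for j in range(k):
                    gw[:, j] = np.einsum("nct,nct->c", g, xp[:, :, j:j + T])
                w._accum(gw)
            if x.requires_grad:
                gxp = np.zeros_like(xp)
                for j in range(k):
                    gxp[:, :, j:j + T] += g * w.data[None, :, j, None]
                x._accum(gxp[:, :, p:p + T])
        out._backward = bw
    return out


# ----------------------------------------------------------------------
class Module:
    training: bool = True

    def parameters(self) -> Iterator[Tensor]:
        seen: set[int] = set()
        for v in self.__dict__.values():
            yield from _params_of(v, seen)

    def train(self, mode: bool = True):
        self.training = mode
        for v in self.__dict__.values():
            for m in _modules_of(v):
                m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data for i, p in enumerate(self.parameters())}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.data = np.asarray(arrays[f"p{i}"], dtype=np.float64)


def _params_of(v, seen):
    if isinstance(v, Tensor) and v.requires_grad and id(v) not in seen:
        seen.add(id(v))
        yield v
    elif isinstance(v, Module):
        for q in v.__dict__.values():
            yield from _params_of(q, seen)
    elif isinstance(v, (list, tuple)):
        for q in v:
            yield from _params_of(q, seen)


def _modules_of(v):
    if isinstance(v, Module):
        yield v
    elif isinstance(v, (list, tuple)):
        for q in v:
            yield from _modules_of(q)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True):
        lim = math.sqrt(6.0 / (d_in + d_out))
        self.w = Tensor(rng.uniform(-lim, lim, size=(d_in, d_out)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.w
        return y + self.b if self.b is not None else y


class Conv1d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator):
        lim = math.sqrt(6.0 / (c_in * kernel + c_out * kernel))
        self.w = Tensor(rng.uniform(-lim, lim, size=(c_out, c_in, kernel)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        return conv1d(x, self.w, self.b, mask=mask)


class DepthwiseConv1d(Module):
    def __init__(self, channels: int, kernel: int, rng: np.random.Generator):
        lim = math.sqrt(6.0 / (2 * kernel))
        self.w = Tensor(rng.uniform(-lim, lim, size=(channels, kernel)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(channels), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return depthwise_conv1d(x, self.w, self.b)


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout must lie in [0, 1), got {p}")
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(keep)


class MultiHeadSelfAttention(Module):
    """Standard scaled dot-product self-attention over (n, T, d)."""

    def __init__(self, d: int, n_heads: int, dropout: float,
                 rng: np.random.Generator):
        if d % n_heads != 0:
            raise ValueError(f"model width {d} not divisible by {n_heads} heads")
        self.d = d
        self.h = n_heads
        self.wq = Linear(d, d, rng)
        self.wk = Linear(d, d, rng)
        self.wv = Linear(d, d, rng)
        self.wo = Linear(d, d, rng)
        self.drop = Dropout(dropout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        n, T, d = x.shape
        dh = d // self.h

        def heads(t: Tensor) -> Tensor:
            return t.reshape(n, T, self.h, dh).transpose(0, 2, 1, 3)

        q, k, v = heads(self.wq(x)), heads(self.wk(x)), heads(self.wv(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dh))
        attn = self.drop(scores.softmax(axis=-1))
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(n, T, d)
        return self.drop(self.wo(ctx))


# ----------------------------------------------------------------------
def cross_entropy(logits: Tensor, labels: np.ndarray,
                  eps: float = 1e-12) -> Tensor:
    """Mean categorical cross-entropy from raw logits (stable log-softmax)."""
    labels = np.asarray(labels, dtype=np.int64)
    n, C = logits.shape
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1, keepdims=True) + eps)
    logp = z - lse
    loss = -logp[np.arange(n), labels].mean()
    out = _make(np.asarray(loss), (logits,))
    if out.requires_grad:
        def bw():
            p = np.exp(logp)
            p[np.arange(n), labels] -= 1.0
            logits._accum(out.grad * p / n)
        out._backward = bw
    return out


class Adam:
    """Adam with decoupled (AdamW-style) weight decay."""

    def __init__(self, params, lr: float = 5e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
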