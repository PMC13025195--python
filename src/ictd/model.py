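"""The ICTD network: dual multi-scale CNN branches feeding transformer
encoders whose feedforward sublayer is the incremental feature feedforward
network (IFFN), plus cosine-DCCA projection heads and a softmax classifier.

Architecture per view
---------------------
1. Two same-padded 1-D convolutions (in -> 64 -> 128 channels, kernel 3,
   ReLU) preserve the timestep count.
2. Multi-scale temporal context: average pooling at kernel sizes
   8..512 (clamped to the sequence length), each pooled map upsampled back
   by nearest-neighbour repetition, then averaged with the unpooled map
   (``merge="concat"`` instead concatenates and projects back with a 1x1
   convolution).
3. Sinusoidal positional encoding is added, then ``n_layers`` encoder
   blocks: multi-head self-attention and an IFFN, each with a residual
   connection and layer normalisation.
4. The per-view encoder outputs are mean-pooled over time; the two pooled
   representations are concatenated for the classifier and separately
   passed through per-view projection heads for the alignment loss.

The IFFN (see :class:`IFFN`) emphasises salient channels: a partial
convolution touches only the leading fraction of channels, a linear map W1
and GELU follow, the channels are split in half, and the first half is
gated elementwise by a depthwise convolution of the second; the gated
product is concatenated with the gate branch to restore full width before
the final map W2 (keeping W1 and W2 square, 128 x 128 at the default
width).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat
from .cosdcca import ProjectionNet, cos_dcca_loss_t
from .layers import (Conv1d, DepthwiseConv1d, Dropout, LayerNorm, Linear,
                     Module, MultiHeadSelfAttention, conv1d)

__all__ = [
    "ModelConfig", "positional_encoding", "multiscale_matrix",
    "MultiScaleCNNBranch", "PartialConv", "partial_conv", "IFFN", "PlainFFN",
    "EncoderBlock", "ICTDModel", "classify",
]

DEFAULT_POOL_KERNELS = (8, 16, 32, 64, 128, 256, 512)


@dataclass(frozen=True)
class ModelConfig:
    """All architecture hyperparameters in one validated place."""

    in_channels: int = 5                 # per-view input channels
    conv1_out: int = 64
    conv2_out: int = 128
    conv_kernel: int = 3
    pool_kernels: tuple[int, ...] = DEFAULT_POOL_KERNELS
    n_heads: int = 8
    n_layers: int = 2
    hidden1: int = 64
    hidden2: int = 128
    dropout: float = 0.3
    pconv_ratio: float = 0.25
    gate_kernel: int = 3
    iffn_autoencoder: bool = False
    iffn_wide_w2: bool = True            # concat gate branch so W2 stays d x d
    use_iffn: bool = True                # False -> plain FFN (ablation)
    merge_mode: str = "average"          # or "concat" (+1x1 projection)
    proj_dim: int = 32                   # cos-DCCA head output o
    fusion: str = "encoder"              # classifier input: "encoder" pooled
                                         # outputs or the "aligned" projections

    def __post_init__(self):
        if self.conv2_out % self.n_heads != 0:
            raise ValueError("conv2_out must be divisible by n_heads")
        if not 0 < self.pconv_ratio <= 1:
            raise ValueError("pconv_ratio must lie in (0, 1]")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if self.merge_mode not in ("average", "concat"):
            raise ValueError(f"unknown merge_mode: {self.merge_mode!r}")
        if self.fusion not in ("encoder", "aligned"):
            raise ValueError(f"unknown fusion: {self.fusion!r}")
        if self.conv2_out % 2 != 0:
            raise ValueError("encoder width must be even (IFFN channel split)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pool_kernels"] = list(self.pool_kernels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "pool_kernels" in d:
            d["pool_kernels"] = tuple(d["pool_kernels"])
        return cls(**d)


# ----------------------------------------------------------------------
def positional_encoding(max_pos: int, d: int) -> np.ndarray:
    """Fixed sinusoidal table: PE[pos, 2i] = sin(pos / 10000^(2i/d)),
    PE[pos, 2i+1] = cos(pos / 10000^(2i/d))."""
    if d < 1 or max_pos < 1:
        raise ValueError("max_pos and d must be >= 1")
    if d % 2 != 0:
        raise ValueError("encoding dimension must be even")
    pos = np.arange(max_pos)[:, None]
    i = np.arange(d // 2)[None, :]
    angle = pos / np.power(10000.0, 2.0 * i / d)
    pe = np.zeros((max_pos, d))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


def multiscale_matrix(T: int, kernels=DEFAULT_POOL_KERNELS) -> np.ndarray:
    """Linear map on the time axis equal to: average of the identity and
    each block-average-then-repeat operator (kernels clamped to T)."""
    mats = [np.eye(T)]
    for k in kernels:
        k = max(1, min(int(k), T))
        m = np.zeros((T, T))
        for a in range(0, T, k):
            b = min(a + k, T)
            m[a:b, a:b] = 1.0 / (b - a)
        mats.append(m)
    return sum(mats) / len(mats)


class MultiScaleCNNBranch(Module):
    """Conv stack (in -> 64 -> 128, ReLU, same padding) + multi-scale merge."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator,
                 in_channels: int | None = None):
        c_in = in_channels if in_channels is not None else cfg.in_channels
        self.cfg = cfg
        self.c_in = c_in
        self.conv1 = Conv1d(c_in, cfg.conv1_out, cfg.conv_kernel, rng)
        self.conv2 = Conv1d(cfg.conv1_out, cfg.conv2_out, cfg.conv_kernel, rng)
        if cfg.merge_mode == "concat":
            k = len(cfg.pool_kernels) + 1
            self.project = Conv1d(cfg.conv2_out * k, cfg.conv2_out, 1, rng)
        self._mix_cache: dict[int, np.ndarray] = {}

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.c_in:
            raise ValueError(
                f"expected {self.c_in} input channels, got {x.shape[1]}")
        h = self.conv1(x).relu()
        h = self.conv2(h).relu()
        T = h.shape[2]
        if self.cfg.merge_mode == "average":
            if T not in self._mix_cache:
                self._mix_cache[T] = multiscale_matrix(T, self.cfg.pool_kernels).T
            return h @ Tensor(self._mix_cache[T])
        maps = [h]
        for k in self.cfg.pool_kernels:
            k = max(1, min(int(k), T))
            m = np.zeros((T, T))
            for a in range(0, T, k):
                b = min(a + k, T)
                m[a:b, a:b] = 1.0 / (b - a)
            maps.append(h @ Tensor(m.T))
        return self.project(concat(maps, axis=1))


# ----------------------------------------------------------------------
def partial_conv(x: Tensor, w: Tensor, b: Tensor | None, ratio: float,
                 mask: np.ndarray | None = None) -> Tensor:
    """Convolve the leading ceil(ratio*C) channels; pass the rest through.

    With a validity mask, convolution outputs are renormalised by the count
    of valid inputs under the kernel (positions with none become zero).
    """
    if not 0 < ratio <= 1:
        raise ValueError("ratio must lie in (0, 1]")
    if w.shape[-1] > 2 * x.shape[2]:
        raise ValueError(
            f"kernel {w.shape[-1]} larger than twice the sequence length")
    C = x.shape[1]
    cp = math.ceil(ratio * C)
    if ratio == 1.0 or cp == C:
        return conv1d(x, w, b, mask=mask)
    head = conv1d(x[:, :cp, :], w, b, mask=mask)
    return concat([head, x[:, cp:, :]], axis=1)


class PartialConv(Module):
    def __init__(self, channels: int, ratio: float, kernel: int,
                 rng: np.random.Generator):
        if not 0 < ratio <= 1:
            raise ValueError("ratio must lie in (0, 1]")
        self.ratio = ratio
        cp = math.ceil(ratio * channels)
        self.conv = Conv1d(cp, cp, kernel, rng)

    def __call__(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        w, k, T = self.conv.w, self.conv.w.shape[-1], x.shape[2]
        if k > 2 * T - 1:
            # short sequences: the centered sub-kernel is the identical map
            c = (k - (2 * T - 1)) // 2
            w = w[:, :, c:k - c]
        return partial_conv(x, w, self.conv.b, self.ratio, mask=mask)


class IFFN(Module):
    """Incremental feature feedforward network over (n, T, d) sequences.

    u = GELU(W1 . PConv(x)); (u1, u2) = channel halves of u;
    r = u1 * DepthwiseConv(u2); output = GELU(W2 . concat(r, u2)).
    With ``wide_w2=False``, W2 maps the half-width gated product directly
    back to full width instead of concatenating.
    """

    def __init__(self, d: int, cfg: ModelConfig, rng: np.random.Generator):
        if d % 2 != 0:
            raise ValueError("IFFN width must be even to split channels")
        self.d = d
        self.cfg = cfg
        self.pconv = PartialConv(d, cfg.pconv_ratio, cfg.conv_kernel, rng)
        self.w1 = Linear(d, d, rng)
        self.gate = DepthwiseConv1d(d // 2, cfg.gate_kernel, rng)
        w2_in = d if cfg.iffn_wide_w2 else d // 2
        self.w2 = Linear(w2_in, d, rng)
        self.drop = Dropout(cfg.dropout, rng)
        if cfg.iffn_autoencoder:
            self.enc = Linear(d, d // 2, rng)
            self.dec = Linear(d // 2, d, rng)

    def __call__(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        n, T, d = x.shape
        if d != self.d:
            raise ValueError(f"IFFN built for width {self.d}, got {d}")
        if self.cfg.iffn_autoencoder:
            x = self.dec(self.enc(x))
        xc = x.transpose(0, 2, 1)                     # (n, d, T)
        p = self.pconv(xc, mask=mask)
        u = self.w1(p.transpose(0, 2, 1)).gelu()      # (n, T, d)
        half = d // 2
        u1 = u[:, :, :half]
        u2 = u[:, :, half:]
        gate = self.gate(u2.transpose(0, 2, 1)).transpose(0, 2, 1)
        r = u1 * gate
        r_full = concat([r, u2], axis=2) if self.cfg.iffn_wide_w2 else r
        return self.drop(self.w2(r_full).gelu())


class PlainFFN(Module):
    """Width-matched two-layer feedforward baseline (the IFFN ablation)."""

    def __init__(self, d: int, cfg: ModelConfig, rng: np.random.Generator):
        self.l1 = Linear(d, d, rng)
        self.l2 = Linear(d, d, rng)
        self.drop = Dropout(cfg.dropout, rng)

    def __call__(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        return self.drop(self.l2(self.l1(x).gelu()))


class EncoderBlock(Module):
    """Pre-input positional encoding (optional) -> self-attention with
    residual + layer norm -> IFFN with residual + layer norm."""

    def __init__(self, d: int, cfg: ModelConfig, rng: np.random.Generator):
        self.attn = MultiHeadSelfAttention(d, cfg.n_heads, cfg.dropout, rng)
        self.ffn = (IFFN(d, cfg, rng) if cfg.use_iffn
                    else PlainFFN(d, cfg, rng))
        self.ln1 = LayerNorm(d)
        self.ln2 = LayerNorm(d)

    def __call__(self, x: Tensor,
                 pos_encoding: np.ndarray | None = None) -> Tensor:
        if pos_encoding is not None:
            x = x + Tensor(pos_encoding[None, :x.shape[1], :])
        h = self.ln1(x + self.attn(x))
        return self.ln2(h + self.ffn(h))


def classify(ml: Tensor | np.ndarray, wy: Tensor | np.ndarray) -> np.ndarray:
    """Softmax(ml . Wy): row-stochastic class probabilities (max-shifted)."""
    ml = ml.data if isinstance(ml, Tensor) else np.asarray(ml, dtype=float)
    wy = wy.data if isinstance(wy, Tensor) else np.asarray(wy, dtype=float)
    logits = ml @ wy
    if logits.shape[1] < 2:
        raise ValueError("classification needs at least two classes")
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ----------------------------------------------------------------------
class ICTDModel(Module):
    """Full dual-view network; forward returns (logits, H1', H2')."""

    def __init__(self, view_dims: tuple[int, int], n_classes: int,
                 cfg: ModelConfig | None = None, seed: int = 0):
        if n_classes < 2:
            raise ValueError("need at least two classes")
        cfg = cfg or ModelConfig()
        self.cfg = cfg
        self.n_classes = n_classes
        self.view_dims = tuple(view_dims)
        ss = np.random.SeedSequence(seed)
        rng = np.random.default_rng(ss)
        d = cfg.conv2_out
        self.branch1 = MultiScaleCNNBranch(cfg, rng, in_channels=view_dims[0])
        self.branch2 = MultiScaleCNNBranch(cfg, rng, in_channels=view_dims[1])
        self.encoder1 = [EncoderBlock(d, cfg, rng) for _ in range(cfg.n_layers)]
        self.encoder2 = [EncoderBlock(d, cfg, rng) for _ in range(cfg.n_layers)]
        self.proj1 = ProjectionNet(d, cfg.proj_dim, rng,
                                   hidden1=cfg.hidden1, hidden2=cfg.hidden2)
        self.proj2 = ProjectionNet(d, cfg.proj_dim, rng,
                                   hidden1=cfg.hidden1, hidden2=cfg.hidden2)
        head_in = 2 * d if cfg.fusion == "encoder" else 2 * cfg.proj_dim
        self.head = Linear(head_in, n_classes, rng)
        self._pe: dict[int, np.ndarray] = {}

    def _encode(self, x: Tensor, branch, blocks) -> Tensor:
        h = branch(x).transpose(0, 2, 1)              # (n, T, d)
        T = h.shape[1]
        if T not in self._pe:
            self._pe[T] = positional_encoding(T, self.cfg.conv2_out)
        for i, blk in enumerate(blocks):
            h = blk(h, pos_encoding=self._pe[T] if i == 0 else None)
        return h.mean(axis=1)                         # (n, d)

    def forward(self, x1: np.ndarray | Tensor, x2: np.ndarray | Tensor
                ) -> tuple[Tensor, Tensor, Tensor]:
        x1 = self._as_sequence(x1, self.view_dims[0])
        x2 = self._as_sequence(x2, self.view_dims[1])
        z1 = self._encode(x1, self.branch1, self.encoder1)
        z2 = self._encode(x2, self.branch2, self.encoder2)
        h1p, h2p = self.proj1(z1), self.proj2(z2)
        if self.cfg.fusion == "aligned":
            logits = self.head(concat([h1p, h2p], axis=1))
        else:
            logits = self.head(concat([z1, z2], axis=1))
        return logits, h1p, h2p

    __call__ = forward

    @staticmethod
    def _as_sequence(x, d_expected: int) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=float))
        if x.ndim == 2:
            # feature-table input: D channels, single timestep
            x = x.reshape(x.shape[0], x.shape[1], 1)
        if x.shape[1] != d_expected:
            raise ValueError(
                f"expected {d_expected} channels, got {x.shape[1]}")
        return x

    def predict_proba(self, x1, x2) -> np.ndarray:
        from .autodiff import no_grad
        self.eval()
        with no_grad():
            logits, _, _ = self.forward(x1, x2)
        z = logits.data - logits.data.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, x1, x2) -> np.ndarray:
        return self.predict_proba(x1, x2).argmax(axis=1)
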