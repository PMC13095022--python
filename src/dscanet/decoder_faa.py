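"""U-shaped decoder with gated (flexible) axial attention.

Axial attention factorizes self-attention along one spatial axis at a
time; with relative positional terms r^q, r^k, r^v and learnable scalar
gates G_Q, G_K, G_V1, G_V2 the width-axis form is

    y_ij = Σ_w softmax_w( q_ijᵀk_iw + G_Q·q_ijᵀr_iw^q + G_K·k_iwᵀr_iw^k )
               · ( G_V1·v_iw + G_V2·r_iw^v )

(and symmetrically along the height axis).  On small medical datasets
relative position terms are hard to learn; the gates let training
down-weight inaccurate positional encodings instead of letting them
pollute the non-local context.  All four gates start at 1 (plain
positional axial attention) and are updated by training.  A 1/√d scale
is applied to the qᵀk term for numerical stability.

An FAA block runs height-axis then width-axis attention, each as a
residual branch with batch normalization; their composition gives every
output position a global receptive field.  The decoder upsamples
stage-by-stage, concatenating skip features (optionally enriched by the
cross-attention modules), with FAA blocks on its deepest stages, and
finishes with a light progressive refinement to full resolution and a
1×1 convolution to a single-channel logit map.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor

__all__ = ["GateSet", "AxialRelPos", "DecoderConfig",
           "GatedAxialAttention1D", "FAABlock", "Decoder"]


@dataclasses.dataclass
class DecoderConfig:
    widths: tuple = (112, 72, 64, 48)    # decoder widths at 1/32, 1/16, 1/8, 1/4
    refine_widths: tuple = (192, 118)    # refinement widths at 1/2 and 1/1
    faa_stages: tuple = (0, 1)           # decoder stages carrying FAA (0 = deepest)
    heads: int = 8
    max_axis: int = 64                   # relative-position table capacity

    def validate(self):
        if len(self.widths) != 4:
            raise ValueError("four decoder stages required")
        if not set(self.faa_stages) <= {0, 1, 2, 3}:
            raise ValueError(f"faa_stages {self.faa_stages} outside 0..3")


class GateSet(nn.Module):
    """The four learnable scalar gates of one axial-attention layer."""

    def __init__(self, init: float = 1.0):
        super().__init__()
        self.g_q = nn.Parameter(np.float32(init))
        self.g_k = nn.Parameter(np.float32(init))
        self.g_v1 = nn.Parameter(np.float32(init))
        self.g_v2 = nn.Parameter(np.float32(init))


class AxialRelPos(nn.Module):
    """Per-head relative position tables r^q, r^k, r^v along one axis.

    Tables cover offsets −(L−1)…L−1 for axis length L ≤ ``max_axis``.
    """

    def __init__(self, head_dim: int, max_axis: int, rng):
        super().__init__()
        self.head_dim, self.max_axis = head_dim, max_axis
        shape = (2 * max_axis - 1, head_dim)
        self.r_q = nn.Parameter(_init_table(rng, shape))
        self.r_k = nn.Parameter(_init_table(rng, shape))
        self.r_v = nn.Parameter(_init_table(rng, shape))

    def offsets(self, length: int) -> np.ndarray:
        if length > self.max_axis:
            raise ValueError(f"axis length {length} exceeds table capacity {self.max_axis}")
        idx = np.arange(length)
        return (idx[:, None] - idx[None, :]) + (self.max_axis - 1)  # (L, L) table rows


def _init_table(rng, shape):
    return np.clip(rng.normal(0, 0.02, shape), -0.04, 0.04).astype(np.float32)


class GatedAxialAttention1D(nn.Module):
    """Gated axial attention along ``axis`` ∈ {height, width} of (B,C,H,W)."""

    def __init__(self, dim: int, heads: int, axis: str, rng, max_axis: int = 64,
                 gate_init: float = 1.0):
        super().__init__()
        if axis not in ("height", "width"):
            raise ValueError(f"axis must be height or width, got {axis!r}")
        if dim % heads:
            raise ValueError(f"dim {dim} not divisible by {heads} heads")
        self.dim, self.heads, self.axis = dim, heads, axis
        self.head_dim = dim // heads
        self.qkv = nn.Conv2d(dim, 3 * dim, 1, rng, bias=False)
        self.proj = nn.Conv2d(dim, dim, 1, rng)
        self.gates = GateSet(gate_init)
        self.relpos = AxialRelPos(self.head_dim, max_axis, rng)

    def forward(self, x):
        B, C, H, W = x.shape
        qkv = self.qkv(x)
        if self.axis == "height":  # attend along H: treat W as batch
            qkv = qkv.transpose(0, 3, 1, 2)  # (B, W, 3C, H)
            L, O = H, W
        else:
            qkv = qkv.transpose(0, 2, 1, 3)  # (B, H, 3C, W)
            L, O = W, H
        h, d = self.heads, self.head_dim
        qkv = qkv.reshape(B * O, 3, h, d, L).transpose(1, 0, 2, 4, 3)  # 3×(B·O, h, L, d)
        q, k, v = qkv[0], qkv[1], qkv[2]

        g = self.gates
        rows = self.relpos.offsets(L).reshape(-1)
        r_q = ad.take(self.relpos.r_q, rows).reshape(L, L, d)  # (i, w, d)
        r_k = ad.take(self.relpos.r_k, rows).reshape(L, L, d)
        r_v = ad.take(self.relpos.r_v, rows).reshape(L, L, d)

        scale = d ** -0.5
        logits = ad.matmul(q, k.transpose(0, 1, 3, 2)) * scale          # q·k
        # q_ij · r_iw^q  — einsum-style via matmul over the shared d axis
        qr = (q.reshape(B * O, h, L, 1, d) * r_q.reshape(1, 1, L, L, d)).sum(axis=-1)
        kr = (k.reshape(B * O, h, 1, L, d) * r_k.reshape(1, 1, L, L, d)).sum(axis=-1)
        logits = logits + g.g_q * qr + g.g_k * kr
        attn = ad.softmax(logits, axis=-1)                              # (B·O, h, L, L)

        ctx = ad.matmul(attn, v) * g.g_v1
        pos = (attn.reshape(B * O, h, L, L, 1) * r_v.reshape(1, 1, L, L, d)).sum(axis=3)
        y = ctx + pos * g.g_v2                                          # (B·O, h, L, d)

        y = y.transpose(0, 1, 3, 2).reshape(B, O, C, L)
        y = y.transpose(0, 2, 3, 1) if self.axis == "height" else y.transpose(0, 2, 1, 3)
        return self.proj(y)


class FAABlock(nn.Module):
    """Height-axis then width-axis gated attention, each residual + BN."""

    def __init__(self, dim: int, heads: int, rng, max_axis: int = 64,
                 gate_init: float = 1.0):
        super().__init__()
        self.attn_h = GatedAxialAttention1D(dim, heads, "height", rng, max_axis, gate_init)
        self.bn_h = nn.BatchNorm2d(dim)
        self.attn_w = GatedAxialAttention1D(dim, heads, "width", rng, max_axis, gate_init)
        self.bn_w = nn.BatchNorm2d(dim)

    def forward(self, x):
        x = x + self.bn_h(self.attn_h(x))
        return x + self.bn_w(self.attn_w(x))


class _UpBlock(nn.Module):
    """2× upsample, concat skip, two 3×3 conv-BN-ReLU."""

    def __init__(self, c_in: int, c_skip: int, c_out: int, rng):
        super().__init__()
        self.conv1 = nn.ConvBNReLU(c_in + c_skip, c_out, 3, rng)
        self.conv2 = nn.ConvBNReLU(c_out, c_out, 3, rng)

    def forward(self, x, skip):
        x = ad.upsample_bilinear(x, (skip.shape[-2], skip.shape[-1]))
        return self.conv2(self.conv1(ad.concatenate([x, skip], axis=1)))


class _RefineBlock(nn.Module):
    def __init__(self, c_in: int, c_out: int, rng):
        super().__init__()
        self.conv1 = nn.ConvBNReLU(c_in, c_out, 3, rng)
        self.conv2 = nn.ConvBNReLU(c_out, c_out, 3, rng)

    def forward(self, x, size):
        return self.conv2(self.conv1(ad.upsample_bilinear(x, size)))


class Decoder(nn.Module):
    """U-shaped decoder over a 4-stage pyramid of encoder widths.

    Stage 0 consumes the deepest (1/32) map; stages 1–3 upsample and
    concatenate the skip at 1/16, 1/8, 1/4.  FAA blocks sit on
    ``faa_stages``.  A progressive refinement (1/2 then full resolution)
    replaces a single large upsampling jump before the logit projection.
    """

    def __init__(self, skip_widths: list, cfg: DecoderConfig, rng,
                 use_faa: bool = True):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        self.use_faa = use_faa
        w = cfg.widths
        self.entry = nn.ConvBNReLU(skip_widths[3], w[0], 1, rng)
        self.up1 = _UpBlock(w[0], skip_widths[2], w[1], rng)
        self.up2 = _UpBlock(w[1], skip_widths[1], w[2], rng)
        self.up3 = _UpBlock(w[2], skip_widths[0], w[3], rng)
        if use_faa:
            self.faa = {s: FAABlock(w[s], cfg.heads, rng, cfg.max_axis)
                        for s in cfg.faa_stages}
            for s, blk in self.faa.items():
                self._modules[f"faa.{s}"] = blk
        self.refine1 = _RefineBlock(w[3], cfg.refine_widths[0], rng)
        self.refine2 = _RefineBlock(cfg.refine_widths[0], cfg.refine_widths[1], rng)
        self.head = nn.Conv2d(cfg.refine_widths[1], 1, 1, rng)
        # background-prior init: foreground is rare, start the logits negative
        self.head.bias.data[:] = -2.0

    def _maybe_faa(self, x, stage: int):
        if self.use_faa and stage in getattr(self, "faa", {}):
            return self.faa[stage](x)
        return x

    def forward(self, pyramid: list, out_size: tuple) -> Tensor:
        """``pyramid``: stage maps [1/4, 1/8, 1/16, 1/32]; returns logits
        (B, 1, H, W) at ``out_size``."""
        x = self._maybe_faa(self.entry(pyramid[3]), 0)
        x = self._maybe_faa(self.up1(x, pyramid[2]), 1)
        x = self._maybe_faa(self.up2(x, pyramid[1]), 2)
        x = self._maybe_faa(self.up3(x, pyramid[0]), 3)
        h, w = out_size
        x = self.refine1(x, (h // 2, w // 2))
        x = self.refine2(x, (h, w))
        return self.head(x)
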