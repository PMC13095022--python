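"""Spatial Cross-Attention: multi-scale token fusion across encoder stages.

Each of the four edge-encoder stages E_i is tokenized to the *same*
token count P by average pooling with a stage-specific pool size
PS/2^(i−1) followed by a per-channel depthwise 1-D projection:

    T_i = DConv1D(Reshape(AvgPool2D(E_i)))       T_i ∈ R^{P×C_i}

The four token sets are layer-normalized and concatenated channel-wise
into T̄_c ∈ R^{P×C_c}.  Queries and keys are projected from T̄_c, values
from each T̄_i, and one shared attention map Softmax(QKᵀ/√d_k) — d_k =
C_c/h_c — re-weights every value stream, so all four scales are refined
by the same cross-scale affinity.  Refined tokens are re-projected
(depthwise 1-D), layer-normalized and passed through GeLU, then mapped
back to feature maps (√P×√P reshape, bilinear upsample, 1×1 conv + BN +
ReLU) for injection into the decoder skip paths.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor

__all__ = ["SCAConfig", "tokenize_pool", "SpatialCrossAttention", "SCAProjectBack"]


@dataclasses.dataclass
class SCAConfig:
    patch_size: int = 8   # PS: stage-1 pool size; stage i pools with PS/2^(i-1)
    heads: int = 4
    target: str = "decoder"  # where refined maps attach: decoder skips or body stages

    def validate(self):
        if self.patch_size % 8:
            raise ValueError("patch_size must be a multiple of 8 so stage 4 pools ≥ 1")
        if self.target not in ("decoder", "body"):
            raise ValueError(f"unknown sca target {self.target!r}")


def tokenize_pool(feature: Tensor, pool: int, stage: int = 0) -> Tensor:
    """Average-pool (kernel = stride = ``pool``) and flatten to (B, P, C)."""
    H, W = feature.shape[-2], feature.shape[-1]
    if H % pool or W % pool:
        raise ValueError(
            f"SCA stage {stage}: spatial dims ({H},{W}) not divisible by pool {pool}")
    x = ad.avg_pool2d(feature, pool) if pool > 1 else feature
    B, C, h, w = x.shape
    return x.reshape(B, C, h * w).transpose(0, 2, 1)


class _StageTokenizer(nn.Module):
    def __init__(self, channels: int, pool: int, rng, stage: int):
        super().__init__()
        self.pool, self.stage = pool, stage
        self.dconv = nn.DepthwiseConv1d(channels, 3, rng)

    def forward(self, feature):
        return self.dconv(tokenize_pool(feature, self.pool, self.stage))


class SpatialCrossAttention(nn.Module):
    """Shared-map cross-attention over four equal-length token sets."""

    def __init__(self, widths: list, cfg: SCAConfig, rng):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        self.widths = list(widths)
        self.c_cat = int(sum(widths))
        if self.c_cat % cfg.heads:
            raise ValueError(f"concatenated width {self.c_cat} not divisible by "
                             f"{cfg.heads} heads")
        for i, w in enumerate(widths):
            if w % cfg.heads:
                raise ValueError(f"stage {i} width {w} not divisible by {cfg.heads} heads")
        pools = [cfg.patch_size // 2 ** i for i in range(4)]
        self.tokenizers = [_StageTokenizer(w, p, rng, i)
                           for i, (w, p) in enumerate(zip(widths, pools))]
        self.norms_in = [nn.LayerNorm(w) for w in widths]
        self.q_proj = nn.DepthwiseConv1d(self.c_cat, 1, rng)
        self.k_proj = nn.DepthwiseConv1d(self.c_cat, 1, rng)
        self.v_projs = [nn.DepthwiseConv1d(w, 1, rng) for w in widths]
        self.out_projs = [nn.DepthwiseConv1d(w, 1, rng) for w in widths]
        self.norms_out = [nn.LayerNorm(w) for w in widths]
        self.last_attention = None  # shared (B, h, P, P) map, for inspection

    def tokenize(self, features: list) -> list:
        if len(features) != 4:
            raise ValueError("expected four encoder stages")
        return [tok(f) for tok, f in zip(self.tokenizers, features)]

    def attend(self, tokens: list) -> list:
        P = tokens[0].shape[1]
        for i, t in enumerate(tokens):
            if t.shape[1] != P:
                raise ValueError(
                    f"stage {i} token count {t.shape[1]} != shared P {P}")
        h = self.cfg.heads
        normed = [norm(t) for norm, t in zip(self.norms_in, tokens)]
        t_cat = ad.concatenate(normed, axis=2)  # (B, P, C_c)
        B = t_cat.shape[0]
        d_k = self.c_cat // h

        def split_heads(t, width):
            return t.reshape(B, P, h, width // h).transpose(0, 2, 1, 3)

        q = split_heads(self.q_proj(t_cat), self.c_cat)
        k = split_heads(self.k_proj(t_cat), self.c_cat)
        attn = ad.softmax(ad.matmul(q, k.transpose(0, 1, 3, 2)) * (d_k ** -0.5), axis=-1)
        self.last_attention = attn.data  # one map shared by all four value streams

        outs = []
        for i, (t_i, width) in enumerate(zip(normed, self.widths)):
            v = split_heads(self.v_projs[i](t_i), width)
            o = ad.matmul(attn, v).transpose(0, 2, 1, 3).reshape(B, P, width)
            o = ad.gelu(self.norms_out[i](self.out_projs[i](o)))
            outs.append(o)
        return outs

    def forward(self, features: list) -> list:
        return self.attend(self.tokenize(features))


class SCAProjectBack(nn.Module):
    """Refined tokens → spatial map: √P×√P reshape, bilinear upsample,
    1×1 conv + BN + ReLU to the requested width."""

    def __init__(self, c_in: int, c_out: int, rng):
        super().__init__()
        self.proj = nn.ConvBNReLU(c_in, c_out, 1, rng)

    def forward(self, tokens: Tensor, target_hw: tuple) -> Tensor:
        B, P, C = tokens.shape
        side = int(round(P ** 0.5))
        if side * side != P:
            raise ValueError(f"token count {P} is not a perfect square")
        x = tokens.transpose(0, 2, 1).reshape(B, C, side, side)
        return self.proj(ad.upsample_bilinear(x, target_hw))
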