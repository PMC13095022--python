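"""Bipolar Fusion: class-token exchange between the shallowest and
deepest feature levels.

Shallow levels localize, deep levels abstract; BF fuses exactly those
two.  Each level is flattened to tokens, summarized by a class token
obtained as global average pooling of the layer-normalized tokens,

    CLS = GAP(Norm(P_level)),

given a learnable positional term, and refined by a small stack of
standard pre-norm transformer encoders (S blocks at the shallow level,
L at the deep one).  The class tokens are then *exchanged*: the shallow
CLS is projected to the deep width (f_s), used as the **single query**
of a cross-attention over [CLS′_s ∥ P_l] — so the attention runs in
time linear in the number of deep tokens — residually updated,

    y_s = f_s(CLS_s) + MCA(LN([f_s(CLS_s) ∥ P_l])),

projected back (g_s) and concatenated onto the shallow tokens,
Z_s = [P_s ∥ g_s(y_s)]; the deep level mirrors the computation.  The
fused token sets, class token dropped, are reshaped back to maps and
replace the corresponding decoder skip connections.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor

__all__ = ["BFConfig", "make_class_token", "LevelEmbedding", "TransformerEncoderBlock",
           "SingleQueryCrossAttention", "BipolarFusion"]


@dataclasses.dataclass
class BFConfig:
    s_blocks: int = 1   # encoders at the shallow (small-width) level
    l_blocks: int = 1   # encoders at the deep (large-width) level
    heads: int = 4
    mlp_ratio: float = 2.0

    def validate(self):
        if self.s_blocks < 1 or self.l_blocks < 1:
            raise ValueError("at least one transformer encoder per level")


def make_class_token(tokens: Tensor, norm: nn.LayerNorm) -> Tensor:
    """CLS = mean over the token axis of the layer-normalized tokens."""
    if tokens.shape[1] < 1:
        raise ValueError("need at least one token")
    return norm(tokens).mean(axis=1, keepdims=True)


@dataclasses.dataclass
class LevelEmbedding:
    """[cls ∥ tokens] sequence for one level; cls sits at index 0."""

    tokens: Tensor  # (B, 1+N, D)
    hs: int
    ws: int

    @property
    def cls(self) -> Tensor:
        return self.tokens[:, :1, :]

    @property
    def patches(self) -> Tensor:
        return self.tokens[:, 1:, :]


class TransformerEncoderBlock(nn.Module):
    """Standard pre-norm encoder: MHSA + residual, MLP + residual."""

    def __init__(self, dim: int, heads: int, rng, mlp_ratio: float = 4.0):
        super().__init__()
        if dim % heads:
            raise ValueError(f"dim {dim} not divisible by {heads} heads")
        self.dim, self.heads = dim, heads
        self.norm1 = nn.LayerNorm(dim)
        self.qkv = nn.Linear(dim, 3 * dim, rng)
        self.proj = nn.Linear(dim, dim, rng)
        self.norm2 = nn.LayerNorm(dim)
        self.fc1 = nn.Linear(dim, int(dim * mlp_ratio), rng)
        self.fc2 = nn.Linear(int(dim * mlp_ratio), dim, rng)

    def forward(self, x):
        B, N, D = x.shape
        h, d = self.heads, self.dim // self.heads
        qkv = self.qkv(self.norm1(x)).reshape(B, N, 3, h, d).transpose(2, 0, 3, 1, 4)
        attn = ad.softmax(ad.matmul(qkv[0], qkv[1].transpose(0, 1, 3, 2)) * d ** -0.5, -1)
        y = ad.matmul(attn, qkv[2]).transpose(0, 2, 1, 3).reshape(B, N, D)
        x = x + self.proj(y)
        return x + self.fc2(ad.gelu(self.fc1(self.norm2(x))))


class SingleQueryCrossAttention(nn.Module):
    """Multi-head cross-attention whose sole query is the class token.

    Keys/values are [cls ∥ patches]; the score matrix is 1×(N+1) per
    head, hence linear cost in the token count.
    """

    def __init__(self, dim: int, heads: int, rng):
        super().__init__()
        if dim % heads:
            raise ValueError(f"dim {dim} not divisible by {heads} heads")
        self.dim, self.heads = dim, heads
        self.norm = nn.LayerNorm(dim)
        self.q = nn.Linear(dim, dim, rng)
        self.kv = nn.Linear(dim, 2 * dim, rng)
        self.proj = nn.Linear(dim, dim, rng)
        self.last_attention = None  # (B, h, 1, N+1)

    def forward(self, cls: Tensor, patches: Tensor) -> Tensor:
        seq = self.norm(ad.concatenate([cls, patches], axis=1))
        B, N1, D = seq.shape
        h, d = self.heads, self.dim // self.heads
        q = self.q(seq[:, :1, :]).reshape(B, 1, h, d).transpose(0, 2, 1, 3)
        kv = self.kv(seq).reshape(B, N1, 2, h, d).transpose(2, 0, 3, 1, 4)
        attn = ad.softmax(ad.matmul(q, kv[0].transpose(0, 1, 3, 2)) * d ** -0.5, -1)
        self.last_attention = attn.data
        y = ad.matmul(attn, kv[1]).transpose(0, 2, 1, 3).reshape(B, 1, D)
        return self.proj(y)


class _Level(nn.Module):
    """Per-level machinery: cls norm, positional term, encoder stack."""

    def __init__(self, dim: int, n_tokens: int, n_blocks: int, heads: int,
                 mlp_ratio: float, rng):
        super().__init__()
        self.dim = dim
        self.cls_norm = nn.LayerNorm(dim)
        self.pos = nn.Parameter(
            np.clip(rng.normal(0, 0.02, (1, n_tokens + 1, dim)), -0.04, 0.04)
            .astype(np.float32))
        self.blocks = [TransformerEncoderBlock(dim, heads, rng, mlp_ratio)
                       for _ in range(n_blocks)]

    def embed(self, tokens: Tensor, hs: int, ws: int) -> LevelEmbedding:
        cls = make_class_token(tokens, self.cls_norm)
        seq = ad.concatenate([cls, tokens], axis=1)
        if seq.shape[1] != self.pos.shape[1]:
            raise ValueError(
                f"level built for {self.pos.shape[1] - 1} tokens, got {seq.shape[1] - 1}")
        return LevelEmbedding(tokens=seq + self.pos, hs=hs, ws=ws)

    def encode(self, emb: LevelEmbedding) -> LevelEmbedding:
        x = emb.tokens
        for blk in self.blocks:
            x = blk(x)
        return LevelEmbedding(tokens=x, hs=emb.hs, ws=emb.ws)


class BipolarFusion(nn.Module):
    """Fuse stage-1 (shallow, width D_s) and stage-4 (deep, width D_l) maps."""

    def __init__(self, d_small: int, d_large: int, n_small: int, n_large: int,
                 cfg: BFConfig, rng):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        self.small = _Level(d_small, n_small, cfg.s_blocks, cfg.heads, cfg.mlp_ratio, rng)
        self.large = _Level(d_large, n_large, cfg.l_blocks, cfg.heads, cfg.mlp_ratio, rng)
        # f: into the other level's width, g: back to own width
        self.f_s = nn.Linear(d_small, d_large, rng)
        self.g_s = nn.Linear(d_large, d_small, rng)
        self.f_l = nn.Linear(d_large, d_small, rng)
        self.g_l = nn.Linear(d_small, d_large, rng)
        self.mca_s = SingleQueryCrossAttention(d_large, cfg.heads, rng)
        self.mca_l = SingleQueryCrossAttention(d_small, cfg.heads, rng)

    def cross_attend(self, small: LevelEmbedding, large: LevelEmbedding):
        """Class-token exchange; returns fused token sets (Z_s, Z_l),
        each with its updated cls re-attached at index 0."""
        cls_s = self.f_s(small.cls)              # CLS′_s in the deep width
        y_s = cls_s + self.mca_s(cls_s, large.patches)
        z_s = ad.concatenate([self.g_s(y_s), small.patches], axis=1)

        cls_l = self.f_l(large.cls)              # mirrored: deep cls → shallow width
        y_l = cls_l + self.mca_l(cls_l, small.patches)
        z_l = ad.concatenate([self.g_l(y_l), large.patches], axis=1)
        return z_s, z_l

    def forward(self, shallow: Tensor, deep: Tensor) -> tuple:
        """Maps in, fused maps out (same spatial dims and widths)."""
        B, Ds, Hs, Ws = shallow.shape
        _, Dl, Hl, Wl = deep.shape
        t_s = shallow.reshape(B, Ds, Hs * Ws).transpose(0, 2, 1)
        t_l = deep.reshape(B, Dl, Hl * Wl).transpose(0, 2, 1)
        emb_s = self.small.encode(self.small.embed(t_s, Hs, Ws))
        emb_l = self.large.encode(self.large.embed(t_l, Hl, Wl))
        z_s, z_l = self.cross_attend(emb_s, emb_l)
        out_s = z_s[:, 1:, :].transpose(0, 2, 1).reshape(B, Ds, Hs, Ws)
        out_l = z_l[:, 1:, :].transpose(0, 2, 1).reshape(B, Dl, Hl, Wl)
        return out_s, out_l
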