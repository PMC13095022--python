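"""Body encoder: hierarchical shifted-window transformer.

Patch embedding splits the image into non-overlapping P×P patches
projected to a C-dimensional space with a learned absolute positional
term.  Each stage alternates window attention (W-MSA) and shifted-window
attention (SW-MSA) block pairs with the pre-norm residual layout

    ẑ = W-MSA(LN(z)) + z ;  z = MLP(LN(ẑ)) + ẑ
    ẑ = SW-MSA(LN(z)) + z ; z = MLP(LN(ẑ)) + ẑ

and patch merging (2×2 concat + linear reduction, doubling the width)
between stages, producing the pyramid H/4×W/4×C … H/32×W/32×8C.
Shifted windows use a cyclic shift with an attention mask so that
tokens wrapped together from non-adjacent image regions cannot attend
to each other.  Window attention carries a learned relative position
bias (toggleable).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor

__all__ = ["BodyConfig", "TokenGrid", "PatchEmbed", "WindowAttention",
           "SwinBlock", "PatchMerging", "BodyEncoder"]


@dataclasses.dataclass
class BodyConfig:
    embed_dim: int = 96
    depths: tuple = (2, 2, 6, 2)
    heads: tuple = (3, 6, 12, 24)
    window_size: int = 7
    patch_size: int = 4
    mlp_ratio: float = 4.0
    rel_pos_bias: bool = True

    def validate(self):
        if len(self.depths) != 4 or len(self.heads) != 4:
            raise ValueError("four stages required")
        for s, h in enumerate(self.heads):
            if (self.embed_dim * 2 ** s) % h:
                raise ValueError(f"stage {s} width not divisible by {h} heads")


@dataclasses.dataclass
class TokenGrid:
    """Token sequence with retained 2-D layout (Hs, Ws)."""

    tokens: Tensor  # (B, Hs*Ws, D)
    hs: int
    ws: int

    def __post_init__(self):
        if self.tokens.shape[1] != self.hs * self.ws:
            raise ValueError("token count does not match grid layout")


def _window_partition(x: Tensor, hs: int, ws: int, win: int) -> Tensor:
    """(B, Hs*Ws, D) -> (B*nW, win*win, D) for a grid divisible by win."""
    B, _, D = x.shape
    x = x.reshape(B, hs // win, win, ws // win, win, D)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(B * (hs // win) * (ws // win), win * win, D)


def _window_reverse(x: Tensor, hs: int, ws: int, win: int, batch: int) -> Tensor:
    D = x.shape[-1]
    x = x.reshape(batch, hs // win, ws // win, win, win, D)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(batch, hs * ws, D)


def _relative_index(side: int, table_win: int) -> np.ndarray:
    """Flat indices into a (2·table_win−1)² offset table for a side×side window."""
    coords = np.stack(np.meshgrid(np.arange(side), np.arange(side), indexing="ij"))
    flat = coords.reshape(2, -1)
    rel = flat[:, :, None] - flat[:, None, :]
    rel = rel.transpose(1, 2, 0) + (table_win - 1)
    return (rel[:, :, 0] * (2 * table_win - 1) + rel[:, :, 1]).astype(np.int64)


def shift_attention_mask(hs: int, ws: int, win: int, shift: int,
                         pad_b: int = 0, pad_r: int = 0) -> np.ndarray:
    """Additive mask (nW, win², win²): −1e9 where two tokens of a cyclically
    shifted (and possibly padded) window come from non-adjacent regions.

    Region labels live in the *rolled* frame: after the cyclic shift the
    last ``shift`` rows/cols hold content wrapped from the opposite image
    side, and the preceding ``win − shift`` band shares windows with it.
    Padded rows/cols (tracked through the roll) form their own region.
    """
    Hp, Wp = hs + pad_b, ws + pad_r
    region = np.zeros((Hp, Wp), dtype=np.int64)
    if shift:
        cnt = 0
        slices = (slice(0, -win), slice(-win, -shift), slice(-shift, None))
        for hsl in slices:
            for wsl in slices:
                region[hsl, wsl] = cnt
                cnt += 1
    valid = np.ones((Hp, Wp), dtype=bool)
    valid[hs:, :] = False
    valid[:, ws:] = False
    if shift:
        valid = np.roll(valid, (-shift, -shift), axis=(0, 1))
    region[~valid] = -1  # padding attends only to padding
    region = region.reshape(Hp // win, win, Wp // win, win).transpose(0, 2, 1, 3)
    region = region.reshape(-1, win * win)
    mask = np.where(region[:, :, None] == region[:, None, :], 0.0, -1e9)
    return mask.astype(np.float32)


class PatchEmbed(nn.Module):
    def __init__(self, cfg: BodyConfig, rng, in_chans: int = 3):
        super().__init__()
        P, C = cfg.patch_size, cfg.embed_dim
        self.patch_size = P
        self.proj = nn.Conv2d(in_chans, C, P, rng, stride=P, padding=0)
        self.norm = nn.LayerNorm(C)
        self._pos = {}
        self._rng_state = rng

    def _pos_embed(self, n_tokens: int, dim: int) -> nn.Parameter:
        # lazily created per token count so one model serves several input sizes
        key = f"pos_{n_tokens}"
        if key not in self._pos:
            p = nn.Parameter(
                np.clip(self._rng_state.normal(0, 0.02, (1, n_tokens, dim)), -0.04, 0.04)
                .astype(np.float32))
            self._pos[key] = p
            self._params[key] = p
        return self._pos[key]

    def forward(self, image) -> TokenGrid:
        if image.shape[-2] % self.patch_size or image.shape[-1] % self.patch_size:
            raise ValueError(
                f"image dims {image.shape[-2:]} not divisible by patch size {self.patch_size}")
        x = self.proj(image)  # (B, C, H/P, W/P)
        B, C, hs, ws = x.shape
        tokens = x.reshape(B, C, hs * ws).transpose(0, 2, 1)
        tokens = self.norm(tokens) + self._pos_embed(hs * ws, C)
        return TokenGrid(tokens=tokens, hs=hs, ws=ws)


class WindowAttention(nn.Module):
    """Multi-head self-attention within win×win windows, with relative
    position bias and optional additive mask for shifted windows."""

    def __init__(self, dim: int, heads: int, win: int, rng, rel_pos_bias: bool = True):
        super().__init__()
        self.dim, self.heads, self.win = dim, heads, win
        self.head_dim = dim // heads
        self.scale = self.head_dim ** -0.5
        self.qkv = nn.Linear(dim, 3 * dim, rng)
        self.proj = nn.Linear(dim, dim, rng)
        self.rel_pos_bias = rel_pos_bias
        if rel_pos_bias:
            self.bias_table = nn.Parameter(
                np.clip(rng.normal(0, 0.02, ((2 * win - 1) ** 2, heads)), -0.04, 0.04)
                .astype(np.float32))
            self._rel_index_cache = {}
        self.last_attention = None  # (nW*B, heads, N, N) ndarray, for inspection

    def _rel_index(self, side: int) -> np.ndarray:
        if side not in self._rel_index_cache:
            self._rel_index_cache[side] = _relative_index(side, self.win)
        return self._rel_index_cache[side]

    def forward(self, x, mask: np.ndarray | None = None):
        B_, N, D = x.shape
        h, d = self.heads, self.head_dim
        qkv = self.qkv(x).reshape(B_, N, 3, h, d).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]  # (B_, h, N, d)
        attn = ad.matmul(q, k.transpose(0, 1, 3, 2)) * self.scale
        if self.rel_pos_bias:
            side = int(round(N ** 0.5))
            bias = ad.take(self.bias_table, self._rel_index(side).reshape(-1))
            bias = bias.reshape(N, N, h).transpose(2, 0, 1)
            attn = attn + bias
        if mask is not None:
            nW = mask.shape[0]
            m = mask[None, :, None, :, :]  # (1, nW, 1, N, N)
            attn = attn.reshape(B_ // nW, nW, h, N, N) + Tensor(m)
            attn = attn.reshape(B_, h, N, N)
        attn = ad.softmax(attn, axis=-1)
        self.last_attention = attn.data
        out = ad.matmul(attn, v).transpose(0, 2, 1, 3).reshape(B_, N, D)
        return self.proj(out)


class _Mlp(nn.Module):
    def __init__(self, dim: int, hidden: int, rng):
        super().__init__()
        self.fc1 = nn.Linear(dim, hidden, rng)
        self.fc2 = nn.Linear(hidden, dim, rng)

    def forward(self, x):
        return self.fc2(ad.gelu(self.fc1(x)))


class SwinBlock(nn.Module):
    """One pre-norm block: (S)W-MSA + residual, then MLP + residual."""

    def __init__(self, dim: int, heads: int, win: int, shift: int, rng,
                 mlp_ratio: float = 4.0, rel_pos_bias: bool = True):
        super().__init__()
        self.win, self.shift = win, shift
        self.norm1 = nn.LayerNorm(dim)
        self.attn = WindowAttention(dim, heads, win, rng, rel_pos_bias=rel_pos_bias)
        self.norm2 = nn.LayerNorm(dim)
        self.mlp = _Mlp(dim, int(dim * mlp_ratio), rng)

    def forward(self, grid: TokenGrid) -> TokenGrid:
        hs, ws = grid.hs, grid.ws
        win = min(self.win, hs, ws)
        shift = min(self.shift, win // 2)
        if win >= hs and win >= ws:
            shift = 0  # a single window spans the grid: shifting is a no-op
        x = self.norm1(grid.tokens)
        B, _, D = x.shape

        pad_b = (-hs) % win
        pad_r = (-ws) % win
        if pad_b or pad_r:
            xm = x.reshape(B, hs, ws, D).transpose(0, 3, 1, 2)
            xm = ad.pad2d(xm, (0, pad_b, 0, pad_r))
            x = xm.transpose(0, 2, 3, 1).reshape(B, (hs + pad_b) * (ws + pad_r), D)
        Hp, Wp = hs + pad_b, ws + pad_r

        if shift:
            x = _roll(x.reshape(B, Hp, Wp, D), -shift).reshape(B, Hp * Wp, D)
        needs_mask = shift > 0 or pad_b or pad_r
        mask = shift_attention_mask(hs, ws, win, shift, pad_b, pad_r) if needs_mask else None

        wins = _window_partition(x, Hp, Wp, win)
        wins = self.attn(wins, mask=mask)
        x = _window_reverse(wins, Hp, Wp, win, B)

        if shift:
            xm = x.reshape(B, Hp, Wp, D)
            xm = _roll(xm, shift)
            x = xm.reshape(B, Hp * Wp, D)
        if pad_b or pad_r:
            xm = x.reshape(B, Hp, Wp, D)
            xm = xm[:, :hs, :ws, :]
            x = xm.reshape(B, hs * ws, D)

        z = grid.tokens + x
        z = z + self.mlp(self.norm2(z))
        return TokenGrid(tokens=z, hs=hs, ws=ws)


def _roll(x: Tensor, shift: int) -> Tensor:
    """Cyclic roll over axes (1, 2) of a (B, H, W, D) tensor."""
    data = np.roll(x.data, (shift, shift), axis=(1, 2))

    def backward(g):
        x._accum(np.roll(g, (-shift, -shift), axis=(1, 2)))

    out = Tensor(data, requires_grad=x.requires_grad, _parents=(x,) if x.requires_grad else ())
    if out.requires_grad:
        out._backward = backward
    return out


class PatchMerging(nn.Module):
    """Concatenate 2×2 token neighborhoods (4D) and reduce to 2D."""

    def __init__(self, dim: int, rng):
        super().__init__()
        self.norm = nn.LayerNorm(4 * dim)
        self.reduction = nn.Linear(4 * dim, 2 * dim, rng, bias=False)

    def forward(self, grid: TokenGrid) -> TokenGrid:
        hs, ws = grid.hs, grid.ws
        B, _, D = grid.tokens.shape
        x = grid.tokens.reshape(B, hs, ws, D)
        if hs % 2 or ws % 2:
            xm = x.transpose(0, 3, 1, 2)
            xm = ad.pad2d(xm, (0, hs % 2, 0, ws % 2))
            x = xm.transpose(0, 2, 3, 1)
            hs, ws = hs + hs % 2, ws + ws % 2
        x = x.reshape(B, hs // 2, 2, ws // 2, 2, D)
        x = x.transpose(0, 1, 3, 2, 4, 5).reshape(B, (hs // 2) * (ws // 2), 4 * D)
        x = self.reduction(self.norm(x))
        return TokenGrid(tokens=x, hs=hs // 2, ws=ws // 2)


class BodyEncoder(nn.Module):
    """Four-stage shifted-window transformer returning a feature pyramid."""

    def __init__(self, cfg: BodyConfig, rng):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        self.widths = [cfg.embed_dim * 2 ** s for s in range(4)]
        self.patch_embed = PatchEmbed(cfg, rng)
        blocks, merges, norms = [], [], []
        for s in range(4):
            dim = self.widths[s]
            stage = []
            for b in range(cfg.depths[s]):
                shift = 0 if b % 2 == 0 else cfg.window_size // 2
                stage.append(SwinBlock(dim, cfg.heads[s], cfg.window_size, shift, rng,
                                       mlp_ratio=cfg.mlp_ratio,
                                       rel_pos_bias=cfg.rel_pos_bias))
            blocks.append(stage)
            norms.append(nn.LayerNorm(dim))
            if s < 3:
                merges.append(PatchMerging(dim, rng))
        self.blocks = [b for stage in blocks for b in stage]
        self._stage_sizes = [len(stage) for stage in blocks]
        self.merges = merges
        self.norms = norms

    def stage_blocks(self, s: int):
        lo = sum(self._stage_sizes[:s])
        return self.blocks[lo:lo + self._stage_sizes[s]]

    def forward(self, image) -> list:
        """Return the 4-stage pyramid as (B, C_s, H_s, W_s) feature maps."""
        if image.shape[-2] % 32 or image.shape[-1] % 32:
            raise ValueError("input spatial dims must be divisible by 32")
        grid = self.patch_embed(image)
        features = []
        for s in range(4):
            for blk in self.stage_blocks(s):
                grid = blk(grid)
            out = self.norms[s](grid.tokens)
            B, _, D = out.shape
            features.append(out.transpose(0, 2, 1).reshape(B, D, grid.hs, grid.ws))
            if s < 3:
                grid = self.merges[s](grid)
        return features
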