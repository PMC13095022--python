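"""Edge encoder: a four-stage CNN built from pixel-difference convolutions.

Pixel Difference Convolution (PDC) replaces the weighted sum of pixel
intensities of a vanilla convolution, y = Σ ω_i·x_i, with a weighted sum
of pixel-pair differences, y = Σ_{(i,i′)∈P} ω_i·(x_i − x_i′), making the
response explicitly gradient-aware: any constant input yields exactly
zero.  With the *central* pair set (every window pixel paired with the
window center) this is algebraically a vanilla convolution with a
modified kernel, which is how it is evaluated here.

Each of the four stages stacks four PDC blocks
(x + pointwise(depthwise_pdc(relu(x)))) at constant width, with 2×2
max-pooling and a channel-doubling 1×1 convolution between stages, and a
per-stage deeply supervised edge head (1×1 conv → sigmoid → bilinear
upsample to input resolution).  A stride-2 conv front end provides the
initial 4× downsampling so stage s sits at 1/2^(s+1) of the input.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor

__all__ = [
    "PDCKernelSpec", "EdgePyramid", "central_pairs", "angular_pairs",
    "pairs_to_kernel", "vanilla_conv", "pdc_conv",
    "PDCConv2d", "PDCBlock", "EdgeStage", "EdgeEncoder",
]


@dataclasses.dataclass
class PDCKernelSpec:
    """A pair set P over a k×k window with one learnable weight per pair."""

    k: int
    pairs: list  # [(i, i_prime)] flat indices into the k×k window
    weights: np.ndarray

    def __post_init__(self):
        if not self.pairs:
            raise ValueError("PDC pair set must be non-empty")
        n = self.k * self.k
        for i, j in self.pairs:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"pair ({i},{j}) outside the {self.k}×{self.k} window")
        if len(self.weights) != len(self.pairs):
            raise ValueError("one weight per pair required")


def central_pairs(k: int = 3) -> list:
    """Every window pixel paired with the window center."""
    c = (k * k) // 2
    return [(i, c) for i in range(k * k)]


def angular_pairs(k: int = 3) -> list:
    """Each ring pixel paired with its clockwise neighbor (3×3 only)."""
    if k != 3:
        raise ValueError("angular pair set defined for 3×3 kernels")
    ring = [0, 1, 2, 5, 8, 7, 6, 3]  # clockwise flat indices around the center
    return [(ring[i], ring[(i + 1) % 8]) for i in range(8)]


def pairs_to_kernel(spec: PDCKernelSpec) -> np.ndarray:
    """Fold a pair-difference kernel into an equivalent vanilla kernel.

    Σ ω·(x_i − x_i′) = Σ ω·x_i − Σ ω·x_i′ — accumulate +ω at i and −ω at i′.
    """
    kern = np.zeros(spec.k * spec.k, dtype=np.float64)
    for (i, j), w in zip(spec.pairs, spec.weights):
        kern[i] += w
        kern[j] -= w
    return kern.reshape(spec.k, spec.k)


def vanilla_conv(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Plain valid cross-correlation of a 2-D array (reference path)."""
    out = ad.conv2d(Tensor(x[None, None].astype(np.float64)),
                    Tensor(kernel[None, None].astype(np.float64)))
    return out.data[0, 0]


def pdc_conv(x: np.ndarray, spec: PDCKernelSpec) -> np.ndarray:
    """Valid pair-difference convolution via the folded kernel."""
    return vanilla_conv(x, pairs_to_kernel(spec))


class PDCConv2d(nn.Module):
    """Depthwise 3×3 PDC layer (one learnable kernel per channel).

    The stored weight parameterizes ω; the effective kernel applied to
    the input is the pair-folded one, so constant inputs map to zero for
    any weight values.
    """

    def __init__(self, channels: int, rng, variant: str = "central"):
        super().__init__()
        if variant == "central":
            pairs = central_pairs(3)
        elif variant == "angular":
            pairs = angular_pairs(3)
        else:
            raise ValueError(f"unknown PDC variant {variant!r}")
        self.variant = variant
        k2 = 9
        # signed incidence map: effective_kernel = A @ omega
        A = np.zeros((k2, len(pairs)), dtype=np.float32)
        for col, (i, j) in enumerate(pairs):
            A[i, col] += 1.0
            A[j, col] -= 1.0
        self.incidence = A
        std = np.sqrt(2.0 / (channels * 9))
        self.omega = nn.Parameter(
            rng.normal(0, std, size=(channels, len(pairs))).astype(np.float32))
        self.bias = nn.Parameter(np.zeros(channels, dtype=np.float32))

    def forward(self, x):
        C = x.shape[1]
        with ad.suspend_macs():  # weight folding is not per-pixel compute
            eff = ad.matmul(self.omega, Tensor(self.incidence.T))  # (C, 9)
            w = eff.reshape(C, 1, 3, 3)
        # replicate padding keeps the zero-response-on-constant property
        # exact at the borders (zero padding would fabricate a step edge)
        return ad.conv2d(ad.pad2d_replicate(x, 1), w, self.bias,
                         padding=0, groups=C)


class PDCBlock(nn.Module):
    """Residual PDC block: x + pointwise(depthwise_pdc(relu(x)))."""

    def __init__(self, channels: int, rng, variant: str = "central"):
        super().__init__()
        self.depthwise = PDCConv2d(channels, rng, variant=variant)
        self.pointwise = nn.Conv2d(channels, channels, 1, rng)

    def forward(self, x):
        return x + self.pointwise(self.depthwise(ad.relu(x)))


class EdgeStage(nn.Module):
    """Four PDC blocks at constant width."""

    def __init__(self, channels: int, rng, n_blocks: int = 4, variant: str = "central"):
        super().__init__()
        self.blocks = [PDCBlock(channels, rng, variant=variant) for _ in range(n_blocks)]

    def forward(self, x):
        for blk in self.blocks:
            x = blk(x)
        return x


class _EdgeHead(nn.Module):
    def __init__(self, channels: int, rng):
        super().__init__()
        self.proj = nn.Conv2d(channels, 1, 1, rng)
        # boundary pixels are rare: start the edge logits negative
        self.proj.bias.data[:] = -2.0

    def forward(self, feat, out_size):
        return ad.upsample_bilinear(ad.sigmoid(self.proj(feat)), out_size)


@dataclasses.dataclass
class EdgePyramid:
    """Four feature stages at 1/4 … 1/32 scale plus four supervised
    full-resolution edge probability maps."""

    features: list
    edge_maps: list


class EdgeEncoder(nn.Module):
    """Four-stage PDC branch with per-stage deep edge supervision.

    Stage widths are C, 2C, 4C, 8C; the front end maps RGB → C with two
    stride-2 convolutions (4× downsampling, matching the body branch's
    patch granularity).
    """

    def __init__(self, rng, base_width: int = 64, variant: str = "central",
                 blocks_per_stage: int = 4):
        super().__init__()
        C = base_width
        self.widths = [C, 2 * C, 4 * C, 8 * C]
        self.stem = nn.Sequential(
            nn.ConvBNReLU(3, C // 2, 3, rng, stride=2),
            nn.ConvBNReLU(C // 2, C, 3, rng, stride=2),
        )
        self.stages = [EdgeStage(w, rng, n_blocks=blocks_per_stage, variant=variant)
                       for w in self.widths]
        self.transitions = [nn.Conv2d(self.widths[i], self.widths[i + 1], 1, rng)
                            for i in range(3)]
        self.heads = [_EdgeHead(w, rng) for w in self.widths]

    def forward(self, image) -> EdgePyramid:
        if image.shape[-1] % 32 or image.shape[-2] % 32:
            raise ValueError("input spatial dims must be divisible by 32")
        out_size = (image.shape[-2], image.shape[-1])
        x = self.stem(image)
        features, edge_maps = [], []
        for s in range(4):
            x = self.stages[s](x)
            features.append(x)
            edge_maps.append(self.heads[s](x, out_size))
            if s < 3:
                x = self.transitions[s](ad.max_pool2d(x, 2))
        return EdgePyramid(features=features, edge_maps=edge_maps)
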