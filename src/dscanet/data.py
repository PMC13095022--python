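"""Polyp image samples: synthetic generation, folder I/O, splits, augmentation.

A sample is an RGB endoscopy-style image with a binary polyp (body) mask
and a binary boundary (edge) mask derived from it.  The synthetic
generator emulates the regimes that make clinical polyp segmentation
hard: blurred boundaries, tiny and large polyps, and variable
color/contrast against a textured mucosal background.  Real datasets in
the Kvasir-SEG / CVC-ClinicDB folder convention (``images/`` and
``masks/`` with matching basenames) are loaded through the same type.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import transform as sktransform

__all__ = [
    "ImageSample", "SyntheticConfig", "SplitSpec",
    "generate_sample", "generate_dataset", "derive_edge_gt",
    "load_folder", "save_dataset", "split", "augment", "resize_to",
]

_RASTER_SUFFIXES = (".png", ".jpg", ".jpeg", ".tif", ".tiff", ".bmp")


@dataclasses.dataclass
class ImageSample:
    """One RGB image with its binary body mask and boundary mask.

    ``image`` is H×W×3 float in [0, 1]; ``mask`` and ``edge`` are H×W
    uint8 arrays containing only {0, 1}.  Every edge pixel lies within a
    one-pixel band of a mask 0↔1 transition.
    """

    image: np.ndarray
    mask: np.ndarray
    edge: np.ndarray
    sample_id: str

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape or self.mask.shape != self.edge.shape:
            raise ValueError(
                f"sample {self.sample_id}: image {self.image.shape[:2]}, "
                f"mask {self.mask.shape}, edge {self.edge.shape} differ")
        for name, arr in (("mask", self.mask), ("edge", self.edge)):
            vals = np.unique(arr)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError(f"sample {self.sample_id}: {name} is not binary")

    @property
    def shape(self) -> tuple:
        return self.mask.shape


@dataclasses.dataclass
class SyntheticConfig:
    """Generator settings; ``seed`` together with the sample index fully
    determines every sample."""

    image_size: int = 224
    n_polyps_range: tuple = (1, 2)
    radius_range: tuple = (0.06, 0.30)    # fraction of image size: tiny .. large
    boundary_blur_sigma: float = 1.5      # pixels of boundary softening
    contrast_range: tuple = (0.15, 0.55)  # polyp-background intensity offset
    color_shift_range: tuple = (-0.15, 0.15)
    noise_sigma: float = 0.02
    seed: int = 0

    def validate(self):
        lo, hi = self.radius_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"radius_range {self.radius_range} outside (0, 0.5]")
        if self.n_polyps_range[0] > self.n_polyps_range[1] or self.n_polyps_range[0] < 0:
            raise ValueError(f"empty n_polyps_range {self.n_polyps_range}")
        if not (0 < self.contrast_range[0] <= self.contrast_range[1] <= 1):
            raise ValueError(f"contrast_range {self.contrast_range} outside (0, 1]")
        if self.image_size < 8:
            raise ValueError("image_size too small")


@dataclasses.dataclass
class SplitSpec:
    train_fraction: float = 0.8
    seed: int = 0

    def validate(self):
        if not (0 < self.train_fraction < 1):
            raise ValueError(f"train_fraction {self.train_fraction} outside (0,1)")


# -- edge ground truth ---------------------------------------------------------

_CROSS = ndimage.generate_binary_structure(2, 1)  # 3×3 cross


def derive_edge_gt(mask: np.ndarray) -> np.ndarray:
    """Boundary band of a binary mask: morphological gradient, binarized.

    Uses a 3×3 cross structuring element with replicate border handling
    (dilation minus erosion of the {0,1} mask), so a constant mask —
    empty or full — has an empty edge except where the object touches
    nothing: a full-ones mask yields no edge because the border is
    replicated rather than zero-padded.
    """
    if not np.isin(np.unique(mask), (0, 1)).all():
        raise ValueError("derive_edge_gt expects a binary {0,1} mask")
    m = mask.astype(bool)
    # replicate-border morphology: pad with edge values, operate, crop
    mp = np.pad(m, 1, mode="edge")
    dil = ndimage.binary_dilation(mp, structure=_CROSS)[1:-1, 1:-1]
    ero = ndimage.binary_erosion(mp, structure=_CROSS)[1:-1, 1:-1]
    return (dil ^ ero).astype(np.uint8)


# -- synthetic generation ------------------------------------------------------

def _star_convex_blob(rng, size: int, center, radius: float, wobble: float = 0.35,
                      n_lobes_max: int = 5) -> np.ndarray:
    """Smooth star-convex blob: radius r(θ) = R·(1 + Σ a_k sin(kθ+φ_k)).

    The radial perturbation total is capped at ``wobble`` so the area
    stays within [ (1-w)², (1+w)² ]·πR².
    """
    n_lobes = rng.integers(2, n_lobes_max + 1)
    amps = rng.uniform(0, 1, n_lobes)
    amps *= wobble / max(amps.sum(), 1e-9) * rng.uniform(0.3, 1.0)
    phases = rng.uniform(0, 2 * math.pi, n_lobes)
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - center[0], xx - center[1]
    theta = np.arctan2(dy, dx)
    r_theta = radius * (1.0 + sum(a * np.sin((k + 1) * theta + p)
                                  for k, (a, p) in enumerate(zip(amps, phases))))
    return (dy ** 2 + dx ** 2) <= r_theta ** 2


def _background(rng, size: int) -> np.ndarray:
    """Low-frequency mucosa-like texture: a sum of 2–4 random sinusoids."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float32) / size
    n_waves = rng.integers(2, 5)
    tex = np.zeros((size, size), dtype=np.float32)
    for _ in range(n_waves):
        fy, fx = rng.uniform(1, 5, 2)
        phase = rng.uniform(0, 2 * math.pi)
        tex += rng.uniform(0.3, 1.0) * np.sin(2 * math.pi * (fy * yy + fx * xx) + phase)
    tex = (tex - tex.min()) / max(float(np.ptp(tex)), 1e-9)
    return tex


def generate_sample(cfg: SyntheticConfig, index: int) -> ImageSample:
    """Deterministically synthesize one polyp sample for (cfg.seed, index)."""
    cfg.validate()
    rng = np.random.default_rng((int(cfg.seed) * 1_000_003 + int(index)) % (2 ** 31))
    size = cfg.image_size

    n_polyps = int(rng.integers(cfg.n_polyps_range[0], cfg.n_polyps_range[1] + 1))
    mask = np.zeros((size, size), dtype=bool)
    for _ in range(n_polyps):
        radius = rng.uniform(*cfg.radius_range) * size
        margin = max(int(radius * 0.5), 1)
        center = rng.uniform(margin, size - margin, 2)
        mask |= _star_convex_blob(rng, size, center, radius)

    # reddish-pink mucosa with a contrast-offset polyp region
    tex = _background(rng, size)
    base_color = np.array([0.55, 0.30, 0.28], dtype=np.float32) \
        + rng.uniform(*cfg.color_shift_range, 3).astype(np.float32)
    image = base_color[None, None, :] * (0.6 + 0.4 * tex[:, :, None])

    contrast = rng.uniform(*cfg.contrast_range)
    sign = 1.0 if rng.uniform() < 0.7 else -1.0  # most polyps brighter than mucosa
    polyp_tint = np.array([1.0, 0.8, 0.7], dtype=np.float32)
    soft = ndimage.gaussian_filter(mask.astype(np.float32), cfg.boundary_blur_sigma)
    image = image + sign * contrast * soft[:, :, None] * polyp_tint[None, None, :]

    image += rng.normal(0, cfg.noise_sigma, image.shape).astype(np.float32)
    image = np.clip(image, 0.0, 1.0).astype(np.float32)

    mask8 = mask.astype(np.uint8)
    tag = "" if mask8.any() or n_polyps == 0 else "_empty"
    if n_polyps > 0 and not mask8.any():
        tag = "_degenerate-empty"
    return ImageSample(image=image, mask=mask8, edge=derive_edge_gt(mask8),
                       sample_id=f"synt_{cfg.seed}_{index:05d}{tag}")


def generate_dataset(cfg: SyntheticConfig, n: int) -> list:
    return [generate_sample(cfg, i) for i in range(n)]


# -- folder I/O ----------------------------------------------------------------

def _find_rasters(folder: Path) -> dict:
    return {p.stem: p for p in sorted(folder.iterdir())
            if p.suffix.lower() in _RASTER_SUFFIXES}


def load_folder(path, layout: str = "generic") -> list:
    """Load paired image/mask rasters from ``path``/images and ``path``/masks.

    ``layout`` may be ``kvasir``, ``clinicdb`` or ``generic``; all three
    follow the same images//masks convention, the name is kept for
    dataset provenance.  Masks are binarized at 127/255 (nominally binary
    masks carry JPEG artifacts) and edge maps are derived on load.
    """
    if layout not in ("kvasir", "clinicdb", "generic"):
        raise ValueError(f"unknown layout {layout!r}")
    path = Path(path)
    img_dir, mask_dir = path / "images", path / "masks"
    for d in (img_dir, mask_dir):
        if not d.is_dir():
            raise FileNotFoundError(f"expected directory {d}")
    images, masks = _find_rasters(img_dir), _find_rasters(mask_dir)
    orphans = sorted(set(images) ^ set(masks))
    if orphans:
        raise ValueError(f"unmatched image/mask basenames: {orphans}")
    samples = []
    for stem in sorted(images):
        try:
            img = np.asarray(Image.open(images[stem]).convert("RGB"), dtype=np.float32) / 255.0
            raw = np.asarray(Image.open(masks[stem]).convert("L"))
        except Exception as exc:  # unreadable raster
            raise IOError(f"cannot read raster pair for {stem!r}: {exc}") from exc
        mask = (raw > 127).astype(np.uint8)
        samples.append(ImageSample(image=img, mask=mask,
                                   edge=derive_edge_gt(mask), sample_id=stem))
    return samples


def save_dataset(samples, out_dir, splits: dict | None = None):
    """Write samples as images//masks//edges/ PNGs plus a TSV manifest."""
    out = Path(out_dir)
    for sub in ("images", "masks", "edges"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    lines = ["sample_id\tsplit\tpolyp_pixels"]
    for s in samples:
        Image.fromarray((s.image * 255).astype(np.uint8)).save(out / "images" / f"{s.sample_id}.png")
        Image.fromarray(s.mask * 255).save(out / "masks" / f"{s.sample_id}.png")
        Image.fromarray(s.edge * 255).save(out / "edges" / f"{s.sample_id}.png")
        part = (splits or {}).get(s.sample_id, "train")
        lines.append(f"{s.sample_id}\t{part}\t{int(s.mask.sum())}")
    (out / "manifest.tsv").write_text("\n".join(lines) + "\n")


# -- splitting -----------------------------------------------------------------

def split(samples: list, spec: SplitSpec) -> tuple:
    """Seeded shuffle-split into (train, test); |train| = round(f·N)."""
    spec.validate()
    n = len(samples)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    n_train = int(round(spec.train_fraction * n))
    if n_train in (0, n):
        raise ValueError(
            f"train_fraction {spec.train_fraction} leaves an empty side for N={n}")
    order = np.random.default_rng(spec.seed).permutation(n)
    train = [samples[i] for i in sorted(order[:n_train])]
    test = [samples[i] for i in sorted(order[n_train:])]
    return train, test


# -- augmentation / resizing ---------------------------------------------------

def augment(sample: ImageSample, rng: np.random.Generator,
            max_rotation: float = 30.0, jitter: float = 0.2) -> ImageSample:
    """Random flips, rotation and color jitter.

    Geometric transforms are applied identically to image, mask and
    edge (masks with nearest-neighbor semantics, re-binarized); color
    jitter in brightness/contrast/saturation touches the image only.
    """
    image, mask, edge = sample.image, sample.mask, sample.edge
    if rng.uniform() < 0.5:
        image, mask, edge = image[:, ::-1], mask[:, ::-1], edge[:, ::-1]
    if rng.uniform() < 0.5:
        image, mask, edge = image[::-1], mask[::-1], edge[::-1]
    angle = rng.uniform(-max_rotation, max_rotation)
    if abs(angle) > 1e-6:
        image = sktransform.rotate(image.astype(np.float64), angle, order=1, mode="edge")
        mask = sktransform.rotate(mask.astype(np.float64), angle, order=0, mode="constant") > 0.5
        edge = sktransform.rotate(edge.astype(np.float64), angle, order=0, mode="constant") > 0.5
    image = np.ascontiguousarray(image, dtype=np.float32)

    brightness = rng.uniform(1 - jitter, 1 + jitter)
    contrast = rng.uniform(1 - jitter, 1 + jitter)
    saturation = rng.uniform(1 - jitter, 1 + jitter)
    image = image * brightness
    mu = image.mean()
    image = (image - mu) * contrast + mu
    gray = image.mean(axis=2, keepdims=True)
    image = gray + (image - gray) * saturation
    image = np.clip(image, 0.0, 1.0).astype(np.float32)

    return ImageSample(image=image, mask=np.ascontiguousarray(mask, dtype=np.uint8),
                       edge=np.ascontiguousarray(edge, dtype=np.uint8),
                       sample_id=sample.sample_id)


def resize_to(sample: ImageSample, size: int) -> ImageSample:
    """Resize to size×size: bilinear for the image, nearest for masks.

    ``size`` must be divisible by 32 so the four-stage encoder pyramid
    (1/4 … 1/32 scales) stays integral.
    """
    if size < 32 or size % 32:
        raise ValueError(
            f"target size {size} must be ≥32 and divisible by 32: the encoders "
            "build a 4-level pyramid down to 1/32 of the input")
    if sample.shape == (size, size):
        return sample
    image = sktransform.resize(sample.image.astype(np.float64), (size, size),
                               order=1, anti_aliasing=False).astype(np.float32)

    def _nearest(arr):
        return sktransform.resize(arr.astype(np.float64), (size, size), order=0,
                                  anti_aliasing=False).astype(np.uint8)

    mask = _nearest(sample.mask)
    return ImageSample(image=image, mask=mask, edge=derive_edge_gt(mask),
                       sample_id=sample.sample_id)
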