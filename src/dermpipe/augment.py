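"""Stochastic train-time image augmentation and the two cropping strategies.

The augmentation families: random brightness/contrast, horizontal and
vertical flips, rotation, isotropic scaling, shear, and CutOut (one square
hole of side 16 by default).  Magnitude ranges are config-exposed defaults;
the method itself fixes only the transform families and the CutOut geometry.

Two train-time input strategies:

* same-sized cropping — a fixed-size window at a uniformly random offset
  (zero-padded first if the image is smaller than the window);
* random-resize cropping — the ImageNet-style operator sampling an area
  fraction and aspect ratio, cropping, then resizing to the input size.

All sampling is driven by an explicit ``numpy.random.Generator`` so full
pipelines are reproducible bit-for-bit from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage.transform import AffineTransform, resize as _sk_resize, warp


@dataclass(frozen=True)
class AugmentParams:
    brightness: float = 0.3  # additive, fraction of 255
    contrast: float = 0.3  # multiplicative, factor in [1-c, 1+c]
    rotation_deg: float = 180.0
    scale_range: tuple[float, float] = (0.8, 1.2)
    shear_deg: float = 10.0
    p_hflip: float = 0.5
    p_vflip: float = 0.5
    cutout_holes: int = 1
    cutout_size: int = 16

    def __post_init__(self) -> None:
        if self.cutout_holes > 0 and self.cutout_size <= 0:
            raise ValueError("cutout_size must be > 0")
        if self.scale_range[0] > self.scale_range[1]:
            raise ValueError("scale_range must be ordered")
        for p in (self.p_hflip, self.p_vflip):
            if not 0 <= p <= 1:
                raise ValueError("flip probabilities must be in [0, 1]")


@dataclass(frozen=True)
class AppliedAugment:
    """One concrete sample of the stochastic transform."""

    brightness: float
    contrast: float
    hflip: bool
    vflip: bool
    rotation_deg: float
    scale: float
    shear_deg: float
    cutout_centers: tuple[tuple[int, int], ...]  # (y, x) per hole
    cutout_size: int


def sample_augment(params: AugmentParams, rng: np.random.Generator, image_shape) -> AppliedAugment:
    h, w = image_shape[:2]
    br = rng.uniform(-params.brightness, params.brightness) if params.brightness > 0 else 0.0
    ct = rng.uniform(1 - params.contrast, 1 + params.contrast) if params.contrast > 0 else 1.0
    hf = bool(rng.random() < params.p_hflip)
    vf = bool(rng.random() < params.p_vflip)
    rot = rng.uniform(-params.rotation_deg, params.rotation_deg) if params.rotation_deg > 0 else 0.0
    lo, hi = params.scale_range
    sc = rng.uniform(lo, hi) if hi > lo else float(lo)
    sh = rng.uniform(-params.shear_deg, params.shear_deg) if params.shear_deg > 0 else 0.0
    centers = tuple(
        (int(rng.integers(0, h)), int(rng.integers(0, w))) for _ in range(params.cutout_holes)
    )
    return AppliedAugment(br, ct, hf, vf, rot, sc, sh, centers, params.cutout_size)


def _apply_geometry(img: np.ndarray, ap: AppliedAugment) -> np.ndarray:
    if ap.rotation_deg == 0 and ap.scale == 1.0 and ap.shear_deg == 0:
        return img
    h, w = img.shape[:2]
    cy, cx = (h - 1) / 2, (w - 1) / 2
    shift = AffineTransform(translation=(-cx, -cy))
    tf = AffineTransform(
        scale=ap.scale,
        rotation=np.deg2rad(ap.rotation_deg),
        shear=np.deg2rad(ap.shear_deg),
    )
    unshift = AffineTransform(translation=(cx, cy))
    chain = shift + tf + unshift
    out = warp(
        img.astype(np.float64), chain.inverse, order=1, mode="constant", cval=0.0,
        preserve_range=True,
    )
    return out


def apply_augment(image: np.ndarray, ap: AppliedAugment) -> np.ndarray:
    """Apply a concrete augmentation sample; identity samples are exact no-ops."""
    img = np.asarray(image)
    dtype = img.dtype
    out = img
    if ap.hflip:
        out = out[:, ::-1]
    if ap.vflip:
        out = out[::-1, :]
    out = _apply_geometry(out, ap)
    if ap.brightness != 0.0 or ap.contrast != 1.0:
        out = out.astype(np.float64) * ap.contrast + ap.brightness * 255.0
    if ap.cutout_size > 0 and ap.cutout_centers:
        out = cutout_at(out, ap.cutout_centers, ap.cutout_size)
    if out is img:
        return img.copy()
    if np.issubdtype(dtype, np.integer):
        return np.rint(np.clip(out, 0, 255)).astype(dtype)
    return np.clip(out, 0, 255).astype(dtype, copy=False)


def random_augment(image: np.ndarray, params: AugmentParams, rng: np.random.Generator) -> np.ndarray:
    """One draw of the composed stochastic augmentation."""
    return apply_augment(image, sample_augment(params, rng, np.asarray(image).shape))


def cutout_at(image: np.ndarray, centers, size: int) -> np.ndarray:
    """Zero square holes of the given side centered at ``(y, x)``, border-clipped."""
    out = np.array(image, copy=True)
    h, w = out.shape[:2]
    half = size // 2
    for (cy, cx) in centers:
        y0, y1 = max(cy - half, 0), min(cy + half, h)
        x0, x1 = max(cx - half, 0), min(cx + half, w)
        if y1 > y0 and x1 > x0:
            out[y0:y1, x0:x1] = 0
    return out


def cutout(image: np.ndarray, holes: int, size: int, rng: np.random.Generator) -> np.ndarray:
    """CutOut: ``holes`` square zero-regions of side ``size`` at uniform centers."""
    img = np.asarray(image)
    if holes == 0:
        return img.copy()
    h, w = img.shape[:2]
    if size > min(h, w):
        raise ValueError(f"cutout size {size} exceeds image side {min(h, w)}")
    centers = [(int(rng.integers(0, h)), int(rng.integers(0, w))) for _ in range(holes)]
    return cutout_at(img, centers, size)


def _pad_to(img: np.ndarray, th: int, tw: int) -> np.ndarray:
    h, w = img.shape[:2]
    if h >= th and w >= tw:
        return img
    ph, pw = max(th - h, 0), max(tw - w, 0)
    pad = [(ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2)]
    if img.ndim == 3:
        pad.append((0, 0))
    return np.pad(img, pad, mode="constant")


def same_size_crop(
    image: np.ndarray, crop_size: tuple[int, int], rng: np.random.Generator
) -> np.ndarray:
    """Fixed-size window at a uniformly random valid offset (pad-then-crop)."""
    th, tw = crop_size
    img = _pad_to(np.asarray(image), th, tw)
    h, w = img.shape[:2]
    oy = int(rng.integers(0, h - th + 1))
    ox = int(rng.integers(0, w - tw + 1))
    return img[oy : oy + th, ox : ox + tw].copy()


def center_crop(image: np.ndarray, crop_size: tuple[int, int]) -> np.ndarray:
    th, tw = crop_size
    img = _pad_to(np.asarray(image), th, tw)
    h, w = img.shape[:2]
    oy, ox = (h - th) // 2, (w - tw) // 2
    return img[oy : oy + th, ox : ox + tw].copy()


def resize_to(image: np.ndarray, crop_size: tuple[int, int]) -> np.ndarray:
    img = np.asarray(image)
    if img.shape[:2] == tuple(crop_size):
        return img.copy()
    out = _sk_resize(
        img.astype(np.float64), crop_size, order=1, anti_aliasing=True, preserve_range=True
    )
    if np.issubdtype(img.dtype, np.integer):
        return np.rint(np.clip(out, 0, 255)).astype(img.dtype)
    return out.astype(img.dtype, copy=False)


def random_resize_crop(
    image: np.ndarray,
    crop_size: tuple[int, int],
    rng: np.random.Generator,
    scale_range: tuple[float, float] = (0.08, 1.0),
    aspect_range: tuple[float, float] = (3.0 / 4.0, 4.0 / 3.0),
    max_tries: int = 10,
) -> np.ndarray:
    """ImageNet-style random-resize crop.

    Samples an area fraction and a (log-uniform) aspect ratio, crops the
    corresponding window at a random position, and resizes it to
    ``crop_size``.  After ``max_tries`` infeasible samples it falls back to
    the largest feasible center crop.
    """
    if scale_range[0] > scale_range[1] or scale_range[0] <= 0:
        raise ValueError("invalid scale_range")
    if aspect_range[0] > aspect_range[1] or aspect_range[0] <= 0:
        raise ValueError("invalid aspect_range")
    img = np.asarray(image)
    h, w = img.shape[:2]
    area = h * w
    for _ in range(max_tries):
        frac = rng.uniform(*scale_range)
        log_aspect = rng.uniform(np.log(aspect_range[0]), np.log(aspect_range[1]))
        aspect = np.exp(log_aspect)
        cw = int(round(np.sqrt(frac * area * aspect)))
        ch = int(round(np.sqrt(frac * area / aspect)))
        if 0 < cw <= w and 0 < ch <= h:
            oy = int(rng.integers(0, h - ch + 1))
            ox = int(rng.integers(0, w - cw + 1))
            return resize_to(img[oy : oy + ch, ox : ox + cw], crop_size)
    side = min(h, w)
    return resize_to(center_crop(img, (side, side)), crop_size)


@dataclass(frozen=True)
class InputStrategy:
    """Train-time input strategy: ``same_sized`` or ``random_resize``."""

    kind: str = "same_sized"
    crop_size: tuple[int, int] = (224, 224)
    rr_scale_range: tuple[float, float] = (0.08, 1.0)
    rr_aspect_range: tuple[float, float] = (3.0 / 4.0, 4.0 / 3.0)

    def __post_init__(self) -> None:
        if self.kind not in ("same_sized", "random_resize"):
            raise ValueError("kind must be 'same_sized' or 'random_resize'")

    def train_view(self, image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "same_sized":
            return same_size_crop(image, self.crop_size, rng)
        return random_resize_crop(
            image, self.crop_size, rng, self.rr_scale_range, self.rr_aspect_range
        )

    def eval_view(self, image: np.ndarray) -> np.ndarray:
        """Single deterministic view used for cheap mid-training evaluation."""
        if self.kind == "same_sized":
            return center_crop(image, self.crop_size)
        side = min(image.shape[0], image.shape[1])
        return resize_to(center_crop(image, (side, side)), self.crop_size)
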