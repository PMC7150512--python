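"""Dermoscopy image preprocessing.

Uncropped dermoscopic images often show the illuminated circular field of
view (FOV) inside a large near-black border.  The preprocessing chain is:

1. binarize at a very low intensity threshold so the whole FOV is foreground;
2. fit the ellipse with the same center of mass and second central moments
   as the foreground region;
3. derive the axis-aligned bounding box of that ellipse;
4. crop only when a heuristic says the box interior is substantially
   brighter than the exterior (i.e. there really is a black border);
5. apply Shades-of-Gray color constancy (Minkowski norm ``p = 6``);
6. resize the longer side of large images down to 600 pixels, preserving
   the aspect ratio (the HAM10000 reference resolution).

All thresholds the method itself leaves open (binarization level, what
"substantially different" means, the illuminant gain) are explicit,
config-exposed parameters here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .records import EllipseParams, FovBox, ImageRecord

logger = logging.getLogger(__name__)

RESIZE_TARGET = 600  # HAM10000 longer-side reference resolution


class NoFieldOfViewError(ValueError):
    """Raised when a binary mask contains no usable foreground region."""


@dataclass(frozen=True)
class ColorConstancyParams:
    """Shades-of-Gray settings.

    ``gain_convention`` fixes the common gray level ``g`` the channels are
    normalized to: ``"mean"`` uses the arithmetic mean of the per-channel
    illuminant estimates (preserves overall brightness).
    """

    p_minkowski: float = 6.0
    gain_convention: str = "mean"

    def __post_init__(self) -> None:
        if self.p_minkowski <= 0:
            raise ValueError("p_minkowski must be > 0")
        if self.gain_convention not in ("mean",):
            raise ValueError(f"unknown gain convention {self.gain_convention!r}")


@dataclass(frozen=True)
class CropHeuristicParams:
    """Crop-necessity heuristic settings.

    Cropping fires only when at least ``min_outside_fraction`` of the pixels
    lie outside the candidate box AND the mean intensity inside is at least
    ``contrast_ratio`` times the mean outside (plus one, guarding against a
    pitch-black exterior).
    """

    binarize_threshold: float = 20.0
    contrast_ratio: float = 2.0
    min_outside_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.binarize_threshold <= 255:
            raise ValueError("binarize_threshold must be in [0, 255]")
        if self.contrast_ratio < 1:
            raise ValueError("contrast_ratio must be >= 1")
        if not 0 <= self.min_outside_fraction <= 1:
            raise ValueError("min_outside_fraction must be in [0, 1]")


def _as_array(image) -> np.ndarray:
    img = image.image if isinstance(image, ImageRecord) else np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    return img


def _mean_channel(img: np.ndarray) -> np.ndarray:
    if img.ndim == 3:
        return img.astype(np.float64).mean(axis=2)
    if img.ndim == 2:
        return img.astype(np.float64)
    raise ValueError(f"expected RGB or grayscale image, got shape {img.shape}")


def binarize_fov(image, threshold: float = 20.0) -> np.ndarray:
    """Binary mask of pixels whose mean channel intensity exceeds ``threshold``.

    With a very low threshold the entire dermoscopy field of view maps to 1
    while the black border (sensor noise) stays 0.
    """
    gray = _mean_channel(_as_array(image))
    return (gray > threshold).astype(np.uint8)


def fit_fov_ellipse(mask: np.ndarray) -> EllipseParams:
    """Ellipse with the same center of mass and second central moments as the mask.

    Semi-axes are ``2 * sqrt(eigenvalue)`` of the second-central-moment
    matrix — the standard equivalent-ellipse convention, under which a
    filled disk of radius ``r`` maps back to semi-axes ``r``.  Coordinates
    use pixel centers ``(x + 0.5, y + 0.5)``.
    """
    mask = np.asarray(mask)
    ys, xs = np.nonzero(mask)
    if len(xs) == 0:
        raise NoFieldOfViewError("no field of view found (all-zero mask)")
    x = xs + 0.5
    y = ys + 0.5
    cx, cy = x.mean(), y.mean()
    dx, dy = x - cx, y - cy
    mxx = dx @ dx / len(x)
    myy = dy @ dy / len(x)
    mxy = dx @ dy / len(x)
    cov = np.array([[mxx, mxy], [mxy, myy]])
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[0] <= 1e-9:
        raise NoFieldOfViewError("degenerate (collinear) field-of-view mask")
    a = 2.0 * np.sqrt(evals[1])
    b = 2.0 * np.sqrt(evals[0])
    vx, vy = evecs[:, 1]
    theta = np.arctan2(vy, vx)
    if theta <= -np.pi / 2:
        theta += np.pi
    elif theta > np.pi / 2:
        theta -= np.pi
    return EllipseParams(cx=float(cx), cy=float(cy), a=float(a), b=float(b), theta=float(theta))


def ellipse_to_bbox(e: EllipseParams, image_shape: tuple[int, int]) -> FovBox:
    """Axis-aligned bounding box of a rotated ellipse, clipped to the frame."""
    h, w = image_shape[:2]
    c, s = np.cos(e.theta), np.sin(e.theta)
    hx = np.sqrt((e.a * c) ** 2 + (e.b * s) ** 2)
    hy = np.sqrt((e.a * s) ** 2 + (e.b * c) ** 2)
    x0 = max(int(np.floor(e.cx - hx)), 0)
    x1 = min(int(np.ceil(e.cx + hx)), w)
    y0 = max(int(np.floor(e.cy - hy)), 0)
    y1 = min(int(np.ceil(e.cy + hy)), h)
    return FovBox(x0, y0, x1, y1)


def needs_cropping(image, box: FovBox, params: CropHeuristicParams = CropHeuristicParams()) -> bool:
    """Decide whether the candidate box marks a genuine bright FOV.

    True iff enough of the image lies outside the box and the interior is
    substantially brighter than the exterior.
    """
    gray = _mean_channel(_as_array(image))
    h, w = gray.shape
    box = box.clip((h, w))
    inside = np.zeros((h, w), dtype=bool)
    inside[box.slice()] = True
    n_out = inside.size - inside.sum()
    if n_out / inside.size < params.min_outside_fraction:
        return False
    mean_in = gray[inside].mean()
    mean_out = gray[~inside].mean()
    return bool(mean_in >= params.contrast_ratio * (mean_out + 1.0))


def auto_crop(
    image, params: CropHeuristicParams = CropHeuristicParams()
) -> tuple[np.ndarray, FovBox | None, bool]:
    """Detect the FOV and crop to it when the border heuristic fires.

    Returns ``(image, box_or_None, cropped_flag)``; degenerate inputs (no
    detectable field of view) come back unchanged with a warning log.
    """
    img = _as_array(image)
    mask = binarize_fov(img, params.binarize_threshold)
    try:
        ellipse = fit_fov_ellipse(mask)
    except NoFieldOfViewError as exc:
        logger.warning("auto_crop: %s; leaving image unchanged", exc)
        return img, None, False
    box = ellipse_to_bbox(ellipse, img.shape)
    if not needs_cropping(img, box, params):
        return img, None, False
    return img[box.slice()], box, True


def shades_of_gray(image, params: ColorConstancyParams = ColorConstancyParams()) -> np.ndarray:
    """Shades-of-Gray color constancy.

    Estimates the illuminant per channel as the Minkowski ``p``-norm mean
    ``e_c = (mean(I_c^p))^(1/p)`` and rescales each channel to a common
    gray ``g`` (arithmetic mean of the estimates): ``I_c' = I_c * g / e_c``.
    ``p = 6`` is the default.  Integer images are clipped back to
    ``[0, 255]`` and returned in their input dtype; float images are
    returned as float64, clipped to ``[0, 255]``.
    """
    img = _as_array(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("shades_of_gray requires an RGB image")
    x = img.astype(np.float64)
    p = params.p_minkowski
    e = np.power(np.mean(np.power(x, p), axis=(0, 1)), 1.0 / p)
    g = e.mean()
    gains = np.ones(3)
    for c in range(3):
        if e[c] <= 0:
            warnings.warn(f"channel {c} is identically zero; left unchanged", stacklevel=2)
        else:
            gains[c] = g / e[c]
    out = x * gains[None, None, :]
    out = np.clip(out, 0, 255)
    if np.issubdtype(img.dtype, np.integer):
        return np.rint(out).astype(img.dtype)
    return out


def resize_longer_side(image, target: int = RESIZE_TARGET) -> np.ndarray:
    """Resize large images so the longer side equals ``target`` pixels.

    Aspect ratio is preserved (within one-pixel rounding); images whose
    longer side is already at or below the target are left untouched.
    Bilinear interpolation with antialiasing.
    """
    img = _as_array(image)
    h, w = img.shape[:2]
    longer = max(h, w)
    if longer <= target:
        return img
    scale = target / longer
    nh, nw = (target, round(w * scale)) if h >= w else (round(h * scale), target)
    out = _sk_resize(
        img.astype(np.float64), (nh, nw), order=1, anti_aliasing=True, preserve_range=True
    )
    if np.issubdtype(img.dtype, np.integer):
        return np.rint(np.clip(out, 0, 255)).astype(img.dtype)
    return out


@dataclass(frozen=True)
class PreprocessParams:
    crop: CropHeuristicParams = CropHeuristicParams()
    color: ColorConstancyParams = ColorConstancyParams()
    resize_target: int = RESIZE_TARGET


def preprocess(record: ImageRecord, params: PreprocessParams = PreprocessParams()) -> ImageRecord:
    """Full chain: auto-crop, Shades-of-Gray, longer-side resize.

    Returns a new :class:`ImageRecord` with provenance flags set.
    """
    img, box, cropped = auto_crop(record.image, params.crop)
    img = shades_of_gray(img, params.color)
    img = resize_longer_side(img, params.resize_target)
    out = record.with_image(img)
    out.cropped = cropped
    out.fov_box = box
    out.preprocessed = True
    return out
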