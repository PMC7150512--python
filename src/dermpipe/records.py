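"""Core record types shared across the pipeline.

Conventions used throughout the package:

* images are ``uint8`` numpy arrays of shape ``(height, width, 3)`` (RGB);
* pixel coordinates are 0-based with ``x`` = column and ``y`` = row;
* boxes are half-open, ``[x0, x1) x [y0, y1)``;
* for geometric moments a pixel ``(x, y)`` is treated as the unit square
  ``[x, x+1) x [y, y+1)`` with center ``(x + 0.5, y + 0.5)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: ISIC 2019 diagnosis classes, in challenge submission order.
CLASS_NAMES = ("MEL", "NV", "BCC", "AK", "BKL", "DF", "VASC", "SCC", "UNK")
N_CLASSES = len(CLASS_NAMES)


@dataclass(frozen=True)
class FovBox:
    """Axis-aligned field-of-view box, half-open pixel coordinates."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError(f"degenerate box {self}")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError(f"negative box origin {self}")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height

    def clip(self, image_shape: tuple[int, int]) -> "FovBox":
        h, w = image_shape[:2]
        return FovBox(max(self.x0, 0), max(self.y0, 0), min(self.x1, w), min(self.y1, h))

    def slice(self) -> tuple[slice, slice]:
        """``(row_slice, col_slice)`` for array indexing."""
        return slice(self.y0, self.y1), slice(self.x0, self.x1)

    def intersection_area(self, other: "FovBox") -> int:
        w = min(self.x1, other.x1) - max(self.x0, other.x0)
        h = min(self.y1, other.y1) - max(self.y0, other.y0)
        return max(w, 0) * max(h, 0)


@dataclass(frozen=True)
class EllipseParams:
    """Equal-second-central-moments ellipse of a binary region.

    ``a >= b`` are the semi-axes; ``theta`` is the orientation of the major
    axis in radians, in ``(-pi/2, pi/2]``, measured from the +x axis.
    """

    cx: float
    cy: float
    a: float
    b: float
    theta: float

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise ValueError(f"require a >= b > 0, got a={self.a}, b={self.b}")


@dataclass
class ImageRecord:
    """An RGB image with identifiers and provenance flags."""

    image: np.ndarray
    image_id: str
    lesion_id: Optional[str] = None
    label: Optional[int] = None
    cropped: bool = False
    preprocessed: bool = False
    fov_box: Optional[FovBox] = None

    def __post_init__(self) -> None:
        img = np.asarray(self.image)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) RGB image, got shape {img.shape}")
        if img.size == 0:
            raise ValueError("empty image")
        self.image = img

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[:2]

    def with_image(self, image: np.ndarray, **flags) -> "ImageRecord":
        rec = replace(self, image=image)
        for k, v in flags.items():
            setattr(rec, k, v)
        return rec


@dataclass
class MetaRecord:
    """Raw patient metadata; ``None`` marks a missing property.

    ``age`` is in years (ISIC groups ages in steps of five years);
    ``site`` is one of the eight ISIC anatomical sites; ``sex`` is
    ``"male"`` or ``"female"``.
    """

    age: Optional[float] = None
    site: Optional[str] = None
    sex: Optional[str] = None


@dataclass
class LesionDataset:
    """In-memory dataset: images with lesion grouping, labels and metadata."""

    records: list[ImageRecord]
    meta: list[MetaRecord]
    labels: np.ndarray  # (n_images,) int class indices
    lesion_ids: np.ndarray  # (n_images,) object / str
    image_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.records)
        if not (len(self.meta) == len(self.labels) == len(self.lesion_ids) == n):
            raise ValueError("dataset fields have inconsistent lengths")
        if not self.image_ids:
            self.image_ids = [r.image_id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)
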