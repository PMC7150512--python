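"""Deterministic multi-view test-time augmentation with softmax averaging.

Two view sets matching the train-time input strategies:

* same-sized cropping → 36 ordered crops on a 6x6 grid whose top-left
  corners are evenly spaced over the valid offsets (corners and center of
  the image are covered);
* random-resize cropping → 16 views: four differently scaled center crops
  (fractions 1.0, 0.875, 0.75, 0.625 of the shorter side) times four flip
  variants (identity, horizontal, vertical, both), each resized to the
  network input size.

The metadata vector is passed unchanged alongside every view and the
softmaxed predictions of all views are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .augment import InputStrategy, _pad_to, center_crop, resize_to
from .ensemble import read_submission, write_submission  # noqa: F401  (submission I/O lives with the prediction surface too)
from .nn import TwoBranchClassifier, softmax
from .training import images_to_batch

N_ORDERED_CROPS = 36  # 6x6 grid
RR_SCALES = (1.0, 0.875, 0.75, 0.625)
RR_FLIPS = ("identity", "h", "v", "hv")
N_RR_VIEWS = len(RR_SCALES) * len(RR_FLIPS)  # 16


@dataclass
class ViewSet:
    kind: str  # "same_sized" | "random_resize"
    views: list[np.ndarray]
    provenance: list[tuple]

    def __post_init__(self) -> None:
        expected = N_ORDERED_CROPS if self.kind == "same_sized" else N_RR_VIEWS
        if len(self.views) != expected:
            raise ValueError(f"{self.kind} strategy requires {expected} views")


def ordered_crops(image: np.ndarray, crop_size: tuple[int, int]) -> ViewSet:
    """6x6 grid of fixed-size crops with evenly spaced top-left corners."""
    th, tw = crop_size
    img = _pad_to(np.asarray(image), th, tw)
    h, w = img.shape[:2]
    ys = np.rint(np.linspace(0, h - th, 6)).astype(int)
    xs = np.rint(np.linspace(0, w - tw, 6)).astype(int)
    views, prov = [], []
    for oy in ys:
        for ox in xs:
            views.append(img[oy : oy + th, ox : ox + tw].copy())
            prov.append((int(oy), int(ox)))
    return ViewSet(kind="same_sized", views=views, provenance=prov)


def _flip(img: np.ndarray, how: str) -> np.ndarray:
    if how == "identity":
        return img
    if how == "h":
        return img[:, ::-1]
    if how == "v":
        return img[::-1, :]
    return img[::-1, ::-1]


def rr_eval_views(image: np.ndarray, crop_size: tuple[int, int],
                  scales: tuple[float, ...] = RR_SCALES) -> ViewSet:
    """Four scaled center crops x four flips, each resized to ``crop_size``."""
    img = np.asarray(image)
    side = min(img.shape[0], img.shape[1])
    views, prov = [], []
    for scale in scales:
        crop = center_crop(img, (max(int(round(side * scale)), 1),) * 2)
        resized = resize_to(crop, crop_size)
        for how in RR_FLIPS:
            views.append(np.ascontiguousarray(_flip(resized, how)))
            prov.append((scale, how))
    return ViewSet(kind="random_resize", views=views, provenance=prov)


def build_views(image: np.ndarray, strategy: InputStrategy) -> ViewSet:
    if strategy.kind == "same_sized":
        return ordered_crops(image, strategy.crop_size)
    return rr_eval_views(image, strategy.crop_size)


@dataclass
class AveragedPrediction:
    probabilities: np.ndarray  # (n_classes,)
    per_view: np.ndarray  # (n_views, n_classes)

    def __post_init__(self) -> None:
        if (self.probabilities < 0).any() or abs(self.probabilities.sum() - 1.0) > 1e-6:
            raise ValueError("averaged prediction is not a probability vector")


def tta_predict(model: TwoBranchClassifier, image: np.ndarray,
                meta: np.ndarray | None, strategy: InputStrategy,
                batch_size: int = 64) -> AveragedPrediction:
    """Average the model's softmax outputs over the deterministic view set.

    The same metadata vector is fed with every view; passing metadata to an
    image-only model (or omitting it for a two-branch model) is an error.
    """
    if meta is not None and not model.uses_meta:
        raise ValueError("metadata passed to an image-only model")
    if meta is None and model.uses_meta:
        raise ValueError("this model requires a metadata vector")
    viewset = build_views(image, strategy)
    per_view = []
    for start in range(0, len(viewset.views), batch_size):
        chunk = viewset.views[start : start + batch_size]
        xb = images_to_batch(chunk)
        mb = None if meta is None else np.tile(np.asarray(meta, float), (len(chunk), 1))
        per_view.append(softmax(model.forward(xb, mb, train=False)))
    per_view = np.concatenate(per_view)
    return AveragedPrediction(probabilities=per_view.mean(axis=0), per_view=per_view)
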