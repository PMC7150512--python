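"""Synthetic dermoscopy fixtures with known ground truth.

Real dermoscopic images frequently show a bright circular field of view
(the illuminated skin seen through the dermatoscope) surrounded by a
near-black border.  The generators here emulate exactly the properties the
pipeline's stages consume — a skin-toned disk inside a noisy black frame, a
class-dependent lesion blob, lesion groups with several images each,
partially missing patient metadata, and per-configuration/per-fold
probability tensors — so that every stage is testable without any real data.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import numpy as np

from .records import CLASS_NAMES, N_CLASSES, FovBox, ImageRecord, LesionDataset, MetaRecord

SITE_NAMES = (
    "anterior torso",
    "head/neck",
    "lateral torso",
    "lower extremity",
    "oral/genital",
    "palms/soles",
    "posterior torso",
    "upper extremity",
)
SEX_NAMES = ("female", "male")

# Base skin tone (RGB) of the illuminated field of view.
_SKIN_TONE = np.array([205.0, 160.0, 140.0])
_SKIN_NOISE_SD = 6.0
# Black border: uniform noise in [0, 10] of 255 mimics sensor noise.
_BORDER_MAX = 10


def _lesion_color(class_index: int) -> np.ndarray:
    """Deterministic, well-separated lesion RGB color per class."""
    hue = (class_index / N_CLASSES + 0.02) % 1.0
    r, g, b = colorsys.hsv_to_rgb(hue, 0.85, 0.55)
    return np.array([r, g, b]) * 255.0


def _lesion_radius_fraction(class_index: int) -> float:
    # Secondary (shape) cue on top of the color cue.
    return 0.14 + 0.015 * class_index


@dataclass(frozen=True)
class SyntheticImageSpec:
    """One synthetic dermoscopy image.

    ``fov_radius = 0`` means a full-frame image without a black border.
    """

    width: int = 600
    height: int = 450
    fov_center: Optional[tuple[float, float]] = None
    fov_radius: float = 0.0
    lesion_class: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(f"invalid image dimensions {self.width}x{self.height}")
        if self.fov_radius < 0:
            raise ValueError("fov_radius must be >= 0")
        if self.fov_radius > min(self.width, self.height) / 2:
            raise ValueError(
                "fov_radius must be <= min(width, height)/2 "
                f"(got {self.fov_radius} for {self.width}x{self.height})"
            )
        if not 0 <= self.lesion_class < N_CLASSES:
            raise ValueError(f"lesion_class must be in 0..{N_CLASSES - 1}")

    @property
    def center(self) -> tuple[float, float]:
        if self.fov_center is not None:
            return self.fov_center
        return (self.width / 2, self.height / 2)


def gen_dermoscopy_image(
    spec: SyntheticImageSpec, *, appearance_class: Optional[int] = None
) -> tuple[ImageRecord, FovBox]:
    """Render one synthetic dermoscopy image and its ground-truth FOV box.

    The image is near-black (uniform noise in ``[0, 10]``) outside the FOV
    disk, skin-toned with Gaussian noise inside, and carries an elliptical
    lesion blob whose color and size depend deterministically on the class.
    The returned box is the axis-aligned box circumscribing the disk,
    clipped to the frame; for ``fov_radius = 0`` it is the whole frame.

    ``appearance_class`` decouples the rendered look from the label — used
    by datasets whose class signal lives in the metadata instead.
    """
    rng = np.random.default_rng(spec.seed)
    w, h = spec.width, spec.height
    cx, cy = spec.center
    r = spec.fov_radius

    # Pixel-center coordinate grids.
    ys = np.arange(h)[:, None] + 0.5
    xs = np.arange(w)[None, :] + 0.5

    skin = _SKIN_TONE[None, None, :] + rng.normal(0.0, _SKIN_NOISE_SD, size=(h, w, 3))

    if r > 0:
        fov = (xs - cx) ** 2 + (ys - cy) ** 2 <= r * r
        border = rng.uniform(0, _BORDER_MAX, size=(h, w, 3))
        img = np.where(fov[:, :, None], skin, border)
        box = FovBox(
            max(int(np.floor(cx - r)), 0),
            max(int(np.floor(cy - r)), 0),
            min(int(np.ceil(cx + r)), w),
            min(int(np.ceil(cy + r)), h),
        )
        lesion_extent = r
    else:
        img = skin
        box = FovBox(0, 0, w, h)
        lesion_extent = min(w, h) / 2

    cls = spec.lesion_class if appearance_class is None else appearance_class
    lr = _lesion_radius_fraction(cls) * 2 * lesion_extent
    # Lesion center jitters but stays well inside the FOV.
    max_off = max(lesion_extent - lr - 2, 0.0)
    ang = rng.uniform(0, 2 * np.pi)
    off = rng.uniform(0, max_off)
    lx, ly = cx + off * np.cos(ang), cy + off * np.sin(ang)
    ecc = rng.uniform(0.7, 1.0)
    la, lb = lr, lr * ecc
    lang = rng.uniform(0, np.pi)
    ca, sa = np.cos(lang), np.sin(lang)
    u = (xs - lx) * ca + (ys - ly) * sa
    v = -(xs - lx) * sa + (ys - ly) * ca
    lesion = (u / max(la, 1e-9)) ** 2 + (v / max(lb, 1e-9)) ** 2 <= 1.0
    color = _lesion_color(cls)[None, None, :] + rng.normal(0.0, 4.0, size=(h, w, 3))
    img = np.where(lesion[:, :, None], color, img)

    img = np.clip(img, 0, 255).astype(np.uint8)
    rec = ImageRecord(
        image=img,
        image_id=f"SYN_{spec.seed:08d}",
        label=spec.lesion_class,
        fov_box=box if r > 0 else None,
    )
    return rec, box


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """A lesion-grouped synthetic dataset.

    ``images_per_lesion`` is a count or an inclusive ``(lo, hi)`` range.
    ``class_signal`` selects where the class is recoverable from:
    ``"image"`` (lesion appearance), ``"meta"`` (appearance is shuffled,
    metadata determines the class) or ``"both"``.
    """

    n_lesions: int = 50
    images_per_lesion: Union[int, tuple[int, int]] = 1
    class_probabilities: Sequence[float] = field(
        default_factory=lambda: tuple([1.0 / N_CLASSES] * N_CLASSES)
    )
    metadata_missing_rates: tuple[float, float, float] = (0.1, 0.1, 0.1)
    seed: int = 0
    width: int = 96
    height: int = 96
    fov_radius_fraction: float = 0.0  # of min(width, height)/2; 0 => full frame
    class_signal: Literal["image", "meta", "both"] = "image"

    def __post_init__(self) -> None:
        if self.n_lesions <= 0:
            raise ValueError("n_lesions must be >= 1")
        p = np.asarray(self.class_probabilities, dtype=float)
        if len(p) != N_CLASSES or abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
            raise ValueError(
                f"class_probabilities must be {N_CLASSES} non-negative values summing to 1"
            )
        for rate in self.metadata_missing_rates:
            if not 0.0 <= rate <= 1.0:
                raise ValueError("metadata_missing_rates must be in [0, 1]")
        if not 0.0 <= self.fov_radius_fraction <= 1.0:
            raise ValueError("fov_radius_fraction must be in [0, 1]")


def _meta_for_class(cls: int, rng: np.random.Generator, informative: bool) -> MetaRecord:
    if informative:
        # Metadata deterministically encodes the class.
        return MetaRecord(age=float(cls * 10), site=SITE_NAMES[cls % 8], sex=SEX_NAMES[cls % 2])
    # Age in {0, 5, ..., 85}, mirroring ISIC's five-year age groups.
    return MetaRecord(
        age=float(rng.integers(0, 18) * 5),
        site=SITE_NAMES[rng.integers(0, len(SITE_NAMES))],
        sex=SEX_NAMES[rng.integers(0, len(SEX_NAMES))],
    )


def gen_lesion_dataset(spec: SyntheticDatasetSpec, *, render_images: bool = True) -> LesionDataset:
    """Generate a lesion-grouped dataset with metadata and known labels.

    Every lesion has one class shared by all its images; metadata is
    lesion-level and each property is knocked out independently at the
    stated missing rate.  With ``render_images=False`` the pixel data is a
    1x1 placeholder — useful when only the grouping structure matters
    (for instance when exercising cross-validation splitting at scale).
    """
    rng = np.random.default_rng(spec.seed)
    p = np.asarray(spec.class_probabilities, dtype=float)
    classes = rng.choice(N_CLASSES, size=spec.n_lesions, p=p / p.sum())

    if isinstance(spec.images_per_lesion, int):
        counts = np.full(spec.n_lesions, spec.images_per_lesion, dtype=int)
    else:
        lo, hi = spec.images_per_lesion
        counts = rng.integers(lo, hi + 1, size=spec.n_lesions)
    if (counts < 1).any():
        raise ValueError("images_per_lesion must be >= 1")

    fov_r = spec.fov_radius_fraction * min(spec.width, spec.height) / 2
    meta_informative = spec.class_signal in ("meta", "both")
    image_informative = spec.class_signal in ("image", "both")

    records: list[ImageRecord] = []
    metas: list[MetaRecord] = []
    labels: list[int] = []
    lesion_ids: list[str] = []
    for li in range(spec.n_lesions):
        cls = int(classes[li])
        lid = f"LES_{spec.seed:04d}_{li:05d}"
        base_meta = _meta_for_class(cls, rng, meta_informative)
        appearance = cls if image_informative else int(rng.integers(0, N_CLASSES))
        for k in range(counts[li]):
            img_seed = int(rng.integers(0, 2**31 - 1))
            if render_images:
                img_spec = SyntheticImageSpec(
                    width=spec.width,
                    height=spec.height,
                    fov_radius=fov_r,
                    lesion_class=cls,
                    seed=img_seed,
                )
                rec, _ = gen_dermoscopy_image(img_spec, appearance_class=appearance)
            else:
                rec = ImageRecord(
                    image=np.zeros((1, 1, 3), dtype=np.uint8),
                    image_id="placeholder",
                    label=cls,
                )
            rec.image_id = f"IMG_{spec.seed:04d}_{li:05d}_{k}"
            rec.lesion_id = lid
            rec.label = cls
            # Metadata missingness is drawn per image, independently per property.
            m = rng.random(3)
            metas.append(
                MetaRecord(
                    age=None if m[0] < spec.metadata_missing_rates[0] else base_meta.age,
                    site=None if m[1] < spec.metadata_missing_rates[1] else base_meta.site,
                    sex=None if m[2] < spec.metadata_missing_rates[2] else base_meta.sex,
                )
            )
            records.append(rec)
            labels.append(cls)
            lesion_ids.append(lid)

    return LesionDataset(
        records=records,
        meta=metas,
        labels=np.asarray(labels, dtype=int),
        lesion_ids=np.asarray(lesion_ids, dtype=object),
    )


@dataclass(frozen=True)
class SyntheticPredictionSpec:
    """Per-configuration, per-fold class-probability tensors.

    ``skill`` in [0, 1] interpolates each row between a symmetric Dirichlet
    draw (chance level at 0) and the one-hot true label (argmax always
    correct at 1).  A sequence gives one skill per configuration.
    """

    n_configs: int = 8
    n_folds: int = 5
    n_images_per_fold: int = 200
    n_classes: int = N_CLASSES
    skill: Union[float, Sequence[float]] = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.n_configs < 1 or self.n_folds < 1 or self.n_images_per_fold < 1:
            raise ValueError("counts must be >= 1")
        skills = self.skills
        if len(skills) != self.n_configs:
            raise ValueError("skill sequence length must equal n_configs")
        if any(not 0.0 <= s <= 1.0 for s in skills):
            raise ValueError("skill must be in [0, 1]")

    @property
    def skills(self) -> tuple[float, ...]:
        if isinstance(self.skill, (int, float)):
            return tuple([float(self.skill)] * self.n_configs)
        return tuple(float(s) for s in self.skill)


def gen_prediction_tensor(spec: SyntheticPredictionSpec):
    """Generate ``(PredictionTensor, labels per fold)`` with known skill.

    Labels are shared across configurations (the folds' held-out images are
    the same for every configuration, as in cross-validation).
    """
    from .ensemble import PredictionTensor  # local import to avoid a cycle

    rng = np.random.default_rng(spec.seed)
    labels = [
        rng.integers(0, spec.n_classes, size=spec.n_images_per_fold)
        for _ in range(spec.n_folds)
    ]
    skills = spec.skills
    probs: list[list[np.ndarray]] = []
    for ci in range(spec.n_configs):
        s = skills[ci]
        fold_probs = []
        for fj in range(spec.n_folds):
            noise = rng.dirichlet(np.ones(spec.n_classes), size=spec.n_images_per_fold)
            onehot = np.eye(spec.n_classes)[labels[fj]]
            fold_probs.append(s * onehot + (1.0 - s) * noise)
        probs.append(fold_probs)
    tensor = PredictionTensor(probs=probs, labels=[l.copy() for l in labels])
    return tensor, labels


# --------------------------------------------------------------------------
# Disk I/O helpers (ISIC-style CSV + PNG), used by the CLI.

def write_isic_csvs(dataset: LesionDataset, out_dir: Path) -> tuple[Path, Path]:
    """Write ISIC-style metadata and ground-truth CSVs for a dataset."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta_rows = []
    gt_rows = []
    for rec, meta in zip(dataset.records, dataset.meta):
        meta_rows.append(
            {
                "image": rec.image_id,
                "age_approx": "" if meta.age is None else meta.age,
                "anatom_site_general": "" if meta.site is None else meta.site,
                "sex": "" if meta.sex is None else meta.sex,
                "lesion_id": rec.lesion_id,
            }
        )
        row = {"image": rec.image_id}
        for i, name in enumerate(CLASS_NAMES):
            row[name] = 1.0 if rec.label == i else 0.0
        gt_rows.append(row)
    meta_path = out_dir / "metadata.csv"
    gt_path = out_dir / "ground_truth.csv"
    pd.DataFrame(meta_rows).to_csv(meta_path, index=False)
    pd.DataFrame(gt_rows).to_csv(gt_path, index=False)
    return meta_path, gt_path


def write_images(dataset: LesionDataset, out_dir: Path) -> list[Path]:
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in dataset.records:
        p = out_dir / f"{rec.image_id}.png"
        Image.fromarray(rec.image).save(p)
        paths.append(p)
    return paths
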