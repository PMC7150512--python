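"""Patient-metadata encoding and train-time metadata dropout.

Age, anatomical site and sex are encoded into an 11-dimensional vector:
eight one-hot site features, two one-hot sex features, and age as a single
numeric feature.  A missing site or sex leaves its whole block zero; a
missing age is encoded as the sentinel ``-5`` (age 0 is a legitimate value,
so 0 cannot mark missingness).  During training each property is
independently knocked out with probability ``p = 0.1`` so the model cannot
associate missingness itself with any class.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .records import MetaRecord
from .synthetic import SEX_NAMES, SITE_NAMES

MISSING_AGE_SENTINEL = -5.0
META_VECTOR_DIM = len(SITE_NAMES) + len(SEX_NAMES) + 1  # 8 + 2 + 1 = 11

_SITE_INDEX = {name: i for i, name in enumerate(SITE_NAMES)}
_SEX_INDEX = {name: i for i, name in enumerate(SEX_NAMES)}


@dataclass(frozen=True)
class MetaDropoutParams:
    """Probability of masking each metadata property during training."""

    p_drop: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_drop <= 1.0:
            raise ValueError("p_drop must be in [0, 1]")


def encode_metadata(rec: MetaRecord) -> np.ndarray:
    """Encode a metadata record as an 11-vector (site 8, sex 2, age 1)."""
    vec = np.zeros(META_VECTOR_DIM, dtype=np.float64)
    if rec.site is not None:
        if rec.site not in _SITE_INDEX:
            raise ValueError(
                f"unknown anatomical site {rec.site!r}; allowed: {sorted(_SITE_INDEX)}"
            )
        vec[_SITE_INDEX[rec.site]] = 1.0
    if rec.sex is not None:
        if rec.sex not in _SEX_INDEX:
            raise ValueError(f"unknown sex {rec.sex!r}; allowed: {sorted(_SEX_INDEX)}")
        vec[len(SITE_NAMES) + _SEX_INDEX[rec.sex]] = 1.0
    if rec.age is not None:
        if rec.age < 0:
            raise ValueError("age must be non-negative")
        vec[-1] = float(rec.age)
    else:
        vec[-1] = MISSING_AGE_SENTINEL
    return vec


def decode_metadata(vec: np.ndarray) -> MetaRecord:
    """Inverse of :func:`encode_metadata` (test helper)."""
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (META_VECTOR_DIM,):
        raise ValueError(f"expected a {META_VECTOR_DIM}-vector")
    site_block = vec[: len(SITE_NAMES)]
    sex_block = vec[len(SITE_NAMES) : len(SITE_NAMES) + len(SEX_NAMES)]
    site = SITE_NAMES[int(site_block.argmax())] if site_block.sum() > 0 else None
    sex = SEX_NAMES[int(sex_block.argmax())] if sex_block.sum() > 0 else None
    age = None if vec[-1] == MISSING_AGE_SENTINEL else float(vec[-1])
    return MetaRecord(age=age, site=site, sex=sex)


def apply_meta_dropout(
    rec: MetaRecord, params: MetaDropoutParams, rng: np.random.Generator
) -> MetaRecord:
    """Independently replace each property by missing with probability ``p_drop``."""
    draws = rng.random(3)
    return replace(
        rec,
        age=None if draws[0] < params.p_drop else rec.age,
        site=None if draws[1] < params.p_drop else rec.site,
        sex=None if draws[2] < params.p_drop else rec.sex,
    )


def read_metadata_csv(path: Path) -> dict[str, MetaRecord]:
    """Read an ISIC-style metadata CSV; empty cells are missing values."""
    df = pd.read_csv(path, dtype={"image": str})
    required = {"image", "age_approx", "anatom_site_general", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata CSV lacks columns: {sorted(missing)}")
    out: dict[str, MetaRecord] = {}
    for _, row in df.iterrows():
        age = row["age_approx"]
        site = row["anatom_site_general"]
        sex = row["sex"]
        out[row["image"]] = MetaRecord(
            age=None if pd.isna(age) or age == "" else float(age),
            site=None if pd.isna(site) or site == "" else str(site),
            sex=None if pd.isna(sex) or sex == "" else str(sex),
        )
    return out
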