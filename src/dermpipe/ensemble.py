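"""Evaluation metric and cross-validation-driven ensemble subset selection.

The ranking metric is the mean sensitivity

    S = (1/C) * sum_i TP_i / (TP_i + FN_i),

the unweighted average of per-class recalls (a.k.a. balanced accuracy),
robust to the severe class imbalance of dermoscopy datasets.

Ensembling: each configuration ``c_i`` (a choice of backbone, input
strategy, resolution, ...) holds ``m`` cross-validation models whose
held-out predictions ``y_ji`` are known.  An exhaustive search over all
nonempty subsets ``C* ⊆ C`` picks the subset whose averaged predictions

    y* = (1/|C*|) * sum_{i in C*} (1/m) * sum_j y_ji

maximize S on the held-out folds.  The search uses the best-checkpoint
models; the last-epoch checkpoints of the selected configurations are then
pooled into the final ensemble for extra variability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .records import CLASS_NAMES

DEFAULT_MAX_CONFIGS = 16


def _to_label_array(predicted: np.ndarray) -> np.ndarray:
    pred = np.asarray(predicted)
    if pred.ndim == 2:
        # argmax tie-break: lowest class index (numpy convention)
        return pred.argmax(axis=1)
    return pred


def mean_sensitivity(y_true, y_pred, n_classes: Optional[int] = None) -> float:
    """Unweighted mean of per-class recalls.

    ``y_pred`` may be hard labels or a probability matrix (reduced by
    argmax).  Classes absent from the truth are excluded from the average,
    with a warning.
    """
    y_true = np.asarray(y_true)
    if y_true.size == 0:
        raise ValueError("empty input")
    pred = _to_label_array(y_pred)
    if pred.shape[0] != y_true.shape[0]:
        raise ValueError("length mismatch between truth and predictions")
    if n_classes is None:
        n_classes = int(max(y_true.max(), pred.max())) + 1
    recalls = []
    absent = []
    for c in range(n_classes):
        support = y_true == c
        if not support.any():
            absent.append(c)
            continue
        recalls.append(np.mean(pred[support] == c))
    if absent:
        warnings.warn(
            f"classes {absent} absent from the truth; excluded from mean sensitivity",
            stacklevel=2,
        )
    return float(np.mean(recalls))


def _partial_auc_above_sensitivity(y_bin: np.ndarray, scores: np.ndarray,
                                   min_tpr: float = 0.8) -> float:
    """Area under specificity(TPR) for TPR in (min_tpr, 1], normalized to [0, 1]."""
    fpr, tpr, _ = roc_curve(y_bin, scores)
    grid = np.linspace(min_tpr, 1.0, 201)
    # ROC as a step curve: specificity at each required sensitivity level.
    fpr_at = np.array([fpr[np.searchsorted(tpr, t, side="left")] for t in grid])
    spec = 1.0 - fpr_at
    return float(np.trapezoid(spec, grid) / (1.0 - min_tpr))


@dataclass
class MetricsReport:
    """Per-class one-vs-rest metrics plus the mean sensitivity."""

    n_classes: int
    mean_sensitivity: float
    auc: list[Optional[float]]
    auc_above_80_sens: list[Optional[float]]
    sensitivity: list[Optional[float]]
    specificity: list[Optional[float]]

    def to_frame(self) -> pd.DataFrame:
        names = list(CLASS_NAMES[: self.n_classes])
        if len(names) < self.n_classes:
            names += [f"class_{i}" for i in range(len(names), self.n_classes)]
        return pd.DataFrame(
            {
                "class": names,
                "auc": self.auc,
                "auc_s80": self.auc_above_80_sens,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def per_class_report(y_true, probs: np.ndarray) -> MetricsReport:
    """AUC, partial AUC above 80% sensitivity, and argmax sensitivity/specificity."""
    y_true = np.asarray(y_true)
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2 or probs.shape[0] != y_true.shape[0]:
        raise ValueError("probability matrix misaligned with truth")
    n_classes = probs.shape[1]
    pred = probs.argmax(axis=1)
    auc: list[Optional[float]] = []
    auc_s: list[Optional[float]] = []
    sens: list[Optional[float]] = []
    spec: list[Optional[float]] = []
    for c in range(n_classes):
        pos = y_true == c
        if pos.all() or not pos.any():
            auc.append(None)
            auc_s.append(None)
            sens.append(None if not pos.any() else float(np.mean(pred[pos] == c)))
            spec.append(None if pos.all() else float(np.mean(pred[~pos] != c)))
            continue
        auc.append(float(roc_auc_score(pos, probs[:, c])))
        auc_s.append(_partial_auc_above_sensitivity(pos.astype(int), probs[:, c]))
        sens.append(float(np.mean(pred[pos] == c)))
        spec.append(float(np.mean(pred[~pos] != c)))
    s = mean_sensitivity(y_true, pred, n_classes=n_classes)
    return MetricsReport(n_classes, s, auc, auc_s, sens, spec)


@dataclass
class PredictionTensor:
    """Held-out class probabilities per (configuration, fold).

    ``probs[i][j]`` is the ``(n_images_j, n_classes)`` probability matrix of
    configuration ``i`` on the held-out images of fold ``j``; ``labels[j]``
    are the aligned true labels, shared by all configurations.
    """

    probs: list[list[np.ndarray]]
    labels: list[np.ndarray]

    def __post_init__(self) -> None:
        if not self.probs or not self.probs[0]:
            raise ValueError("empty prediction tensor")
        m = len(self.labels)
        for i, fold_probs in enumerate(self.probs):
            if len(fold_probs) != m:
                raise ValueError(f"configuration {i} has {len(fold_probs)} folds, expected {m}")
            for j, p in enumerate(fold_probs):
                p = np.asarray(p, dtype=float)
                if p.ndim != 2 or p.shape[0] != len(self.labels[j]):
                    raise ValueError(f"cell ({i},{j}) misaligned with fold labels")
                if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
                    raise ValueError(f"cell ({i},{j}) rows are not probability vectors")
                self.probs[i][j] = p

    @property
    def n_configs(self) -> int:
        return len(self.probs)

    @property
    def n_folds(self) -> int:
        return len(self.labels)

    def pooled_labels(self) -> np.ndarray:
        return np.concatenate(self.labels)


def ensemble_average(tensor: PredictionTensor, subset: Sequence[int]) -> list[np.ndarray]:
    """Per-fold held-out predictions averaged over a configuration subset."""
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be nonempty")
    out = []
    for j in range(tensor.n_folds):
        out.append(np.mean([tensor.probs[i][j] for i in subset], axis=0))
    return out


def _pooled_s(tensor: PredictionTensor, subset: Sequence[int]) -> float:
    avg = ensemble_average(tensor, subset)
    return mean_sensitivity(tensor.pooled_labels(), np.concatenate(avg))


@dataclass
class EnsembleSelection:
    """Result of the exhaustive subset search."""

    subset: tuple[int, ...]
    predictions: list[np.ndarray]  # per-fold averaged y*
    mean_sensitivity: float
    per_fold_sensitivity: list[float]
    search_log: list[tuple[tuple[int, ...], float]] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "subset": list(self.subset),
            "mean_sensitivity": self.mean_sensitivity,
            "per_fold_sensitivity": self.per_fold_sensitivity,
            "n_subsets_evaluated": len(self.search_log),
        }


def exhaustive_subset_search(
    tensor: PredictionTensor, max_configs: int = DEFAULT_MAX_CONFIGS
) -> EnsembleSelection:
    """Evaluate all ``2^n - 1`` nonempty configuration subsets; return the best.

    The objective is the mean sensitivity of the subset-averaged predictions
    pooled over the held-out folds; per-fold values are logged as well.
    Ties prefer the smaller subset, then lexicographic order (subsets are
    enumerated in that order and only strict improvements replace the
    incumbent), so the search is deterministic.
    """
    n = tensor.n_configs
    if n > max_configs:
        raise ValueError(
            f"{n} configurations exceed the cap {max_configs}; "
            "raise max_configs explicitly to search anyway"
        )
    best_subset: tuple[int, ...] | None = None
    best_s = -np.inf
    log: list[tuple[tuple[int, ...], float]] = []
    for size in range(1, n + 1):
        for subset in combinations(range(n), size):
            s = _pooled_s(tensor, subset)
            log.append((subset, s))
            if s > best_s:
                best_s, best_subset = s, subset
    avg = ensemble_average(tensor, best_subset)
    per_fold = [
        mean_sensitivity(tensor.labels[j], avg[j]) for j in range(tensor.n_folds)
    ]
    return EnsembleSelection(
        subset=best_subset,
        predictions=avg,
        mean_sensitivity=float(best_s),
        per_fold_sensitivity=per_fold,
        search_log=log,
    )


def pool_best_last(
    selection: EnsembleSelection, best: PredictionTensor, last: PredictionTensor
) -> list[np.ndarray]:
    """Final predictions: mean over best AND last models of the chosen subset."""
    if best.n_configs != last.n_configs or best.n_folds != last.n_folds:
        raise ValueError("best/last tensors misaligned")
    for j in range(best.n_folds):
        if len(best.labels[j]) != len(last.labels[j]) or not np.array_equal(
            best.labels[j], last.labels[j]
        ):
            raise ValueError("best/last tensors misaligned (labels differ)")
    avg_best = ensemble_average(best, selection.subset)
    avg_last = ensemble_average(last, selection.subset)
    return [(b + l) / 2.0 for b, l in zip(avg_best, avg_last)]


def write_submission(predictions, path: Path) -> Path:
    """Write an ISIC-style submission CSV (image + 9 class probabilities).

    ``predictions`` is a mapping or an iterable of ``(image_id, 9-vector)``
    pairs; duplicate image ids are rejected.
    """
    items = list(predictions.items()) if isinstance(predictions, dict) else list(predictions)
    ids = [i for i, _ in items]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate image ids")
    rows = []
    for image_id, p in items:
        p = np.asarray(p, dtype=float)
        if p.shape != (len(CLASS_NAMES),):
            raise ValueError(f"prediction for {image_id} must be a {len(CLASS_NAMES)}-vector")
        rows.append({"image": image_id, **{n: v for n, v in zip(CLASS_NAMES, p)}})
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_submission(path: Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, dtype={"image": str})
    if list(df.columns) != ["image"] + list(CLASS_NAMES):
        raise ValueError("unexpected submission header")
    if df["image"].duplicated().any():
        raise ValueError("duplicate image ids")
    return {
        row["image"]: np.array([row[n] for n in CLASS_NAMES], dtype=float)
        for _, row in df.iterrows()
    }
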