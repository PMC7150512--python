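"""Class-balanced training of the two-branch classifier with lesion-grouped CV.

Protocol:

* lesion-grouped k-fold splits (all images of a lesion share a fold, so no
  lesion leaks between training and validation; extra data can be flagged
  train-only and then joins every training set);
* weighted cross-entropy, each class scaled by ``n_i = (N / N_i)^k`` with
  ``k = 1`` (underrepresented classes weigh more);
* Adam, learning rate halved every 25 epochs, 100 epochs by default;
* held-out mean sensitivity evaluated every 10 epochs; the best-scoring
  snapshot (``best``) and the final one (``last``) are both kept;
* a second, metadata stage: the CNN weights are frozen, the dense metadata
  branch, fusion layer and classifier are trained (50 epochs, learning
  rate 1e-5, batch 20 by default) with image augmentation still active and
  metadata dropout applied.

Desk-scale experiments shrink epochs/batches through the same configs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dataclass_field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .augment import AugmentParams, InputStrategy, random_augment
from .ensemble import mean_sensitivity
from .metadata import MetaDropoutParams, apply_meta_dropout, encode_metadata
from .nn import Adam, MetaBranchSpec, TinyConvNet, TwoBranchClassifier, build_two_branch_model, softmax
from .records import LesionDataset

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Loss balancing

@dataclass(frozen=True)
class ClassWeights:
    counts: tuple[int, ...]
    k: float
    weights: tuple[float, ...]

    @property
    def n_total(self) -> int:
        return int(sum(self.counts))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=np.float64)


def class_weights(counts: Sequence[int], k: float = 1.0) -> ClassWeights:
    """Per-class loss weights ``n_i = (N / N_i)^k`` with ``N = sum(N_i)``."""
    counts = tuple(int(c) for c in counts)
    if any(c <= 0 for c in counts):
        raise ValueError("cannot weight a class with zero images")
    n = sum(counts)
    weights = tuple((n / c) ** k for c in counts)
    return ClassWeights(counts=counts, k=float(k), weights=weights)


def weighted_cross_entropy(log_probs: np.ndarray, labels: np.ndarray,
                           weights: ClassWeights | np.ndarray) -> float:
    """Mean over the batch of ``n_y * (-log p_y)``.

    Takes log-probabilities; the weight of each sample is its true class's
    balancing factor.  The mean is over samples (no renormalization by the
    batch weight sum).
    """
    log_probs = np.asarray(log_probs, dtype=float)
    labels = np.asarray(labels)
    if log_probs.ndim != 2 or log_probs.shape[0] != labels.shape[0]:
        raise ValueError("log_probs and labels are misaligned")
    w = weights.as_array() if isinstance(weights, ClassWeights) else np.asarray(weights, float)
    if labels.max() >= len(w):
        raise ValueError("weights do not cover all classes")
    picked = log_probs[np.arange(len(labels)), labels]
    return float(np.mean(-w[labels] * picked))


def lr_schedule(epoch: int, base_lr: float, halving_period: int = 25) -> float:
    """Learning rate halved every ``halving_period`` epochs."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return base_lr * 0.5 ** (epoch // halving_period)


# --------------------------------------------------------------------------
# Lesion-grouped cross-validation

@dataclass
class CVSplit:
    """Lesion-level fold assignment; ``-1`` marks train-only lesions."""

    fold_of: dict
    n_folds: int

    def __post_init__(self) -> None:
        folds = {f for f in self.fold_of.values() if f >= 0}
        if folds and folds != set(range(self.n_folds)):
            raise ValueError("folds must cover 0..n_folds-1")

    def image_folds(self, lesion_ids: Sequence) -> np.ndarray:
        return np.asarray([self.fold_of[l] for l in lesion_ids], dtype=int)

    def val_indices(self, fold: int, lesion_ids: Sequence) -> np.ndarray:
        return np.flatnonzero(self.image_folds(lesion_ids) == fold)

    def train_indices(self, fold: int, lesion_ids: Sequence) -> np.ndarray:
        f = self.image_folds(lesion_ids)
        return np.flatnonzero((f != fold))  # includes train-only (-1)


def grouped_kfold(lesion_ids: Sequence, n_folds: int = 5, seed: int = 0,
                  train_only: Optional[Sequence] = None) -> CVSplit:
    """Partition lesions into folds; every image of a lesion lands in one fold.

    Lesions are shuffled by the seed and dealt round-robin, balancing fold
    sizes to within one lesion.  Lesions listed in ``train_only`` (external
    data) get fold ``-1`` and are included in every training set but no
    validation set.
    """
    train_only = set(train_only or ())
    unique = list(pd.unique(np.asarray(lesion_ids, dtype=object)))
    cv_lesions = [l for l in unique if l not in train_only]
    if len(cv_lesions) < n_folds:
        raise ValueError(f"need at least {n_folds} lesions, got {len(cv_lesions)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cv_lesions))
    fold_of = {l: -1 for l in train_only}
    for pos, idx in enumerate(order):
        fold_of[cv_lesions[idx]] = pos % n_folds
    return CVSplit(fold_of=fold_of, n_folds=n_folds)


# --------------------------------------------------------------------------
# Configs and checkpoints

@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    lr_halving_period: int = 25
    eval_period: int = 10
    base_lr: float = 1e-3
    batch_size: int = 32
    num_classes: int = 9
    k_balance: float = 1.0
    seed: int = 0
    input_size: tuple[int, int] = (64, 64)
    strategy: InputStrategy = InputStrategy(kind="same_sized", crop_size=(64, 64))
    augment: AugmentParams = AugmentParams(rotation_deg=0.0, shear_deg=0.0,
                                           scale_range=(1.0, 1.0))


@dataclass(frozen=True)
class MetaTrainConfig:
    epochs: int = 50
    lr: float = 1e-5
    batch_size: int = 20
    eval_period: int = 10
    meta_dropout: MetaDropoutParams = MetaDropoutParams(0.1)
    meta_spec: MetaBranchSpec = MetaBranchSpec()
    seed: int = 0
    cnn_frozen: bool = True

    def __post_init__(self) -> None:
        if not self.cnn_frozen:
            raise ValueError("the CNN must remain frozen during the metadata stage")


@dataclass
class Checkpoint:
    kind: str  # "best" | "last"
    epoch: int
    state: list[np.ndarray]
    mean_sensitivity: float


@dataclass
class FoldResult:
    fold: int
    best: Checkpoint
    last: Checkpoint
    history: list[tuple[int, float]] = dataclass_field(default_factory=list)
    uses_meta: bool = False


def images_to_batch(images: Sequence[np.ndarray]) -> np.ndarray:
    """Stack HWC uint8 images into a normalized NCHW float batch in [0, 1]."""
    arr = np.stack([np.asarray(im, dtype=np.float64) / 255.0 for im in images])
    return arr.transpose(0, 3, 1, 2)


def _weight_vector(labels: np.ndarray, n_classes: int, k: float) -> np.ndarray:
    counts = np.bincount(labels, minlength=n_classes)
    n = counts.sum()
    w = np.zeros(n_classes)
    present = counts > 0
    w[present] = (n / counts[present]) ** k
    return w


def _train_steps(model: TwoBranchClassifier, opt: Adam, xb: np.ndarray,
                 labels: np.ndarray, w: np.ndarray, meta: Optional[np.ndarray]) -> float:
    logits = model.forward(xb, meta, train=True)
    probs = softmax(logits)
    b = len(labels)
    picked = np.clip(probs[np.arange(b), labels], 1e-12, None)
    loss = float(np.mean(-w[labels] * np.log(picked)))
    if not np.isfinite(loss):
        raise RuntimeError(f"training diverged: non-finite loss {loss}")
    onehot = np.eye(logits.shape[1])[labels]
    glogits = w[labels][:, None] * (probs - onehot) / b
    opt.zero_grad()
    model.backward(glogits)
    opt.step()
    return loss


def evaluate_fold(model: TwoBranchClassifier, dataset: LesionDataset,
                  indices: np.ndarray, strategy: InputStrategy,
                  batch_size: int = 64, use_meta: bool = False) -> float:
    """Held-out mean sensitivity using one deterministic center view per image."""
    preds = []
    for start in range(0, len(indices), batch_size):
        chunk = indices[start : start + batch_size]
        views = [strategy.eval_view(dataset.records[i].image) for i in chunk]
        xb = images_to_batch(views)
        mb = None
        if use_meta:
            mb = np.stack([encode_metadata(dataset.meta[i]) for i in chunk])
        logits = model.forward(xb, mb, train=False)
        preds.append(logits.argmax(axis=1))
    return mean_sensitivity(dataset.labels[indices], np.concatenate(preds))


def _maybe_checkpoint(model, epoch, s, best):
    # strict improvement keeps the earlier epoch on ties (less overfit)
    if best is None or s > best.mean_sensitivity:
        return Checkpoint("best", epoch, model.get_state(), s)
    return best


def train_fold_cnn(dataset: LesionDataset, train_idx: np.ndarray, val_idx: np.ndarray,
                   config: TrainConfig, fold: int,
                   backbone_factory: Optional[Callable] = None) -> FoldResult:
    """Stage 1: train an image-only model on one fold."""
    rng = np.random.default_rng([config.seed, fold, 0])
    model_seed = int(np.random.default_rng([config.seed, fold, 1]).integers(0, 2**31 - 1))
    factory = backbone_factory or (lambda s: TinyConvNet(config.input_size,
                                                         rng=np.random.default_rng(s)))
    model = build_two_branch_model(factory(model_seed), None,
                                   n_classes=config.num_classes, seed=model_seed)
    opt = Adam(model.trainable_params(), lr=config.base_lr)
    labels = dataset.labels
    w = _weight_vector(labels[train_idx], config.num_classes, config.k_balance)

    best: Optional[Checkpoint] = None
    history: list[tuple[int, float]] = []
    for epoch in range(config.epochs):
        opt.lr = lr_schedule(epoch, config.base_lr, config.lr_halving_period)
        order = rng.permutation(len(train_idx))
        for start in range(0, len(order), config.batch_size):
            idx = train_idx[order[start : start + config.batch_size]]
            views = []
            for i in idx:
                v = config.strategy.train_view(dataset.records[i].image, rng)
                views.append(random_augment(v, config.augment, rng))
            _train_steps(model, opt, images_to_batch(views), labels[idx], w, None)
        if (epoch + 1) % config.eval_period == 0 or epoch == config.epochs - 1:
            s = evaluate_fold(model, dataset, val_idx, config.strategy)
            history.append((epoch, s))
            best = _maybe_checkpoint(model, epoch, s, best)
            logger.info("fold %d epoch %d: held-out S = %.4f", fold, epoch, s)
    last_s = history[-1][1] if history else float("nan")
    last = Checkpoint("last", config.epochs - 1, model.get_state(), last_s)
    return FoldResult(fold=fold, best=best, last=last, history=history)


def train_cnn(dataset: LesionDataset, split: CVSplit, config: TrainConfig,
              backbone_factory: Optional[Callable] = None) -> list[FoldResult]:
    """Stage 1 over all folds: per-fold (best, last) checkpoints."""
    results = []
    for fold in range(split.n_folds):
        tr = split.train_indices(fold, dataset.lesion_ids)
        va = split.val_indices(fold, dataset.lesion_ids)
        results.append(train_fold_cnn(dataset, tr, va, config, fold, backbone_factory))
    return results


def build_meta_model_from_checkpoint(checkpoint: Checkpoint, config: TrainConfig,
                                     meta_config: MetaTrainConfig, fold: int,
                                     backbone_factory: Optional[Callable] = None
                                     ) -> TwoBranchClassifier:
    """Attach the metadata branch to a frozen stage-1 backbone."""
    model_seed = int(np.random.default_rng([config.seed, fold, 1]).integers(0, 2**31 - 1))
    factory = backbone_factory or (lambda s: TinyConvNet(config.input_size,
                                                         rng=np.random.default_rng(s)))
    # Rebuild the image-only model to recover the backbone arrays in order.
    donor = build_two_branch_model(factory(model_seed), None,
                                   n_classes=config.num_classes, seed=model_seed)
    donor.load_state(checkpoint.state)
    meta_seed = int(np.random.default_rng([meta_config.seed, fold, 2]).integers(0, 2**31 - 1))
    model = build_two_branch_model(factory(model_seed), meta_config.meta_spec,
                                   n_classes=config.num_classes, seed=meta_seed)
    n_bb = len(model.backbone.state_arrays())
    for dst, src in zip(model.backbone.state_arrays(), donor.backbone.state_arrays()[:n_bb]):
        dst[...] = src
    model.freeze_backbone()
    return model


def train_fold_meta(dataset: LesionDataset, train_idx: np.ndarray, val_idx: np.ndarray,
                    checkpoint: Checkpoint, config: TrainConfig,
                    meta_config: MetaTrainConfig, fold: int,
                    backbone_factory: Optional[Callable] = None) -> FoldResult:
    """Stage 2: train metadata branch + fusion + classifier over a frozen CNN.

    Image augmentation stays active (the CNN's features are not fixed per
    image) and metadata properties are randomly dropped.
    """
    model = build_meta_model_from_checkpoint(checkpoint, config, meta_config, fold,
                                             backbone_factory)
    frozen_hash = model.backbone_hash()
    rng = np.random.default_rng([meta_config.seed, fold, 3])
    opt = Adam(model.trainable_params(), lr=meta_config.lr)
    labels = dataset.labels
    w = _weight_vector(labels[train_idx], config.num_classes, config.k_balance)

    best: Optional[Checkpoint] = None
    history: list[tuple[int, float]] = []
    for epoch in range(meta_config.epochs):
        order = rng.permutation(len(train_idx))
        for start in range(0, len(order), meta_config.batch_size):
            idx = train_idx[order[start : start + meta_config.batch_size]]
            views, metas = [], []
            for i in idx:
                v = config.strategy.train_view(dataset.records[i].image, rng)
                views.append(random_augment(v, config.augment, rng))
                rec = apply_meta_dropout(dataset.meta[i], meta_config.meta_dropout, rng)
                metas.append(encode_metadata(rec))
            _train_steps(model, opt, images_to_batch(views), labels[idx], w,
                         np.stack(metas))
        if (epoch + 1) % meta_config.eval_period == 0 or epoch == meta_config.epochs - 1:
            s = evaluate_fold(model, dataset, val_idx, config.strategy, use_meta=True)
            history.append((epoch, s))
            best = _maybe_checkpoint(model, epoch, s, best)
            logger.info("meta fold %d epoch %d: held-out S = %.4f", fold, epoch, s)
    if model.backbone_hash() != frozen_hash:
        raise RuntimeError("freeze contract violated: backbone changed during meta stage")
    last_s = history[-1][1] if history else float("nan")
    last = Checkpoint("last", meta_config.epochs - 1, model.get_state(), last_s)
    return FoldResult(fold=fold, best=best, last=last, history=history, uses_meta=True)


def train_meta(dataset: LesionDataset, split: CVSplit, cnn_results: list[FoldResult],
               config: TrainConfig, meta_config: MetaTrainConfig,
               backbone_factory: Optional[Callable] = None) -> list[FoldResult]:
    """Stage 2 over all folds, starting from the stage-1 best checkpoints."""
    if len(cnn_results) != split.n_folds:
        raise ValueError("need one stage-1 result per fold")
    results = []
    for fold in range(split.n_folds):
        tr = split.train_indices(fold, dataset.lesion_ids)
        va = split.val_indices(fold, dataset.lesion_ids)
        results.append(
            train_fold_meta(dataset, tr, va, cnn_results[fold].best, config,
                            meta_config, fold, backbone_factory)
        )
    return results
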