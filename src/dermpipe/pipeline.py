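"""End-to-end orchestration: fixtures → preprocess → train → predict → ensemble.

A single :class:`ExperimentConfig` (loadable from YAML) drives every stage;
each stage writes its artifacts under the experiment directory, stamped
with the seed and a hash of the configuration, and can be resumed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .augment import AugmentParams, InputStrategy
from .ensemble import (
    EnsembleSelection,
    PredictionTensor,
    ensemble_average,
    exhaustive_subset_search,
    mean_sensitivity,
    pool_best_last,
    write_submission,
)
from .metadata import MetaDropoutParams, encode_metadata
from .preprocessing import PreprocessParams, preprocess
from .records import LesionDataset
from .synthetic import SyntheticDatasetSpec, gen_lesion_dataset
from .training import (
    Checkpoint,
    FoldResult,
    MetaTrainConfig,
    TrainConfig,
    grouped_kfold,
    train_cnn,
    train_meta,
)
from .nn import MetaBranchSpec, TinyConvNet, build_two_branch_model
from .tta import tta_predict

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfigurationSpec:
    """One ensemble member: a named input-strategy/backbone choice."""

    name: str
    strategy_kind: str = "same_sized"
    crop_size: tuple[int, int] = (64, 64)

    def strategy(self) -> InputStrategy:
        return InputStrategy(kind=self.strategy_kind, crop_size=tuple(self.crop_size))


@dataclass(frozen=True)
class ExperimentConfig:
    seed: int = 0
    out_dir: str = "experiment"
    n_folds: int = 2
    use_meta: bool = False
    dataset: SyntheticDatasetSpec = field(default_factory=SyntheticDatasetSpec)
    configurations: tuple[ConfigurationSpec, ...] = (
        ConfigurationSpec(name="tiny_ss"),
        ConfigurationSpec(name="tiny_rr", strategy_kind="random_resize"),
    )
    train: TrainConfig = field(default_factory=lambda: TrainConfig(epochs=4, eval_period=2))
    meta_train: MetaTrainConfig = field(default_factory=lambda: MetaTrainConfig(epochs=4, lr=1e-3, eval_period=2))
    max_configs: int = 16

    def config_hash(self) -> str:
        return hashlib.sha256(repr(self).encode()).hexdigest()[:12]

    @staticmethod
    def from_yaml(path: Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return ExperimentConfig.from_dict(raw)

    @staticmethod
    def from_dict(raw: dict) -> "ExperimentConfig":
        kwargs = dict(raw)
        if "dataset" in kwargs:
            d = dict(kwargs["dataset"])
            if "images_per_lesion" in d and isinstance(d["images_per_lesion"], list):
                d["images_per_lesion"] = tuple(d["images_per_lesion"])
            kwargs["dataset"] = SyntheticDatasetSpec(**d)
        if "configurations" in kwargs:
            kwargs["configurations"] = tuple(
                ConfigurationSpec(**{**c, "crop_size": tuple(c.get("crop_size", (64, 64)))})
                for c in kwargs["configurations"]
            )
        if "train" in kwargs:
            t = dict(kwargs["train"])
            if "strategy" in t:
                t["strategy"] = InputStrategy(**{**t["strategy"],
                                                 "crop_size": tuple(t["strategy"].get("crop_size", (64, 64)))})
            if "augment" in t:
                t["augment"] = AugmentParams(**t["augment"])
            if "input_size" in t:
                t["input_size"] = tuple(t["input_size"])
            kwargs["train"] = TrainConfig(**t)
        if "meta_train" in kwargs:
            mt = dict(kwargs["meta_train"])
            if isinstance(mt.get("meta_dropout"), dict):
                mt["meta_dropout"] = MetaDropoutParams(**mt["meta_dropout"])
            if isinstance(mt.get("meta_spec"), dict):
                ms = dict(mt["meta_spec"])
                if "hidden" in ms:
                    ms["hidden"] = tuple(ms["hidden"])
                mt["meta_spec"] = MetaBranchSpec(**ms)
            kwargs["meta_train"] = MetaTrainConfig(**mt)
        return ExperimentConfig(**kwargs)


def _stamp(config: ExperimentConfig) -> dict:
    return {"seed": config.seed, "config_hash": config.config_hash()}


@dataclass
class PipelineArtifacts:
    dataset: LesionDataset
    split: object
    fold_results: dict[str, list[FoldResult]]
    best_tensor: PredictionTensor
    last_tensor: PredictionTensor
    selection: EnsembleSelection
    final_predictions: list[np.ndarray]
    report: dict


def _predict_tensor(dataset: LesionDataset, split, config: ExperimentConfig,
                    fold_results: dict[str, list[FoldResult]],
                    which: str) -> PredictionTensor:
    """TTA held-out predictions for every configuration and fold."""
    labels = []
    val_sets = []
    for fold in range(split.n_folds):
        va = split.val_indices(fold, dataset.lesion_ids)
        val_sets.append(va)
        labels.append(dataset.labels[va])
    probs = []
    for cspec in config.configurations:
        results = fold_results[cspec.name]
        strategy = cspec.strategy()
        tc = replace(config.train, strategy=strategy)
        fold_probs = []
        for fold in range(split.n_folds):
            ckpt: Checkpoint = getattr(results[fold], which)
            if config.use_meta:
                # stage-2 checkpoints carry the full two-branch state
                model = _load_meta_model(ckpt, tc, config, fold)
            else:
                model = _load_image_model(ckpt, tc, config, fold)
            rows = []
            for i in val_sets[fold]:
                meta = encode_metadata(dataset.meta[i]) if config.use_meta else None
                rows.append(tta_predict(model, dataset.records[i].image, meta,
                                        strategy).probabilities)
            fold_probs.append(np.stack(rows))
        probs.append(fold_probs)
    return PredictionTensor(probs=probs, labels=labels)


def _model_seed(config: ExperimentConfig, fold: int) -> int:
    return int(np.random.default_rng([config.train.seed, fold, 1]).integers(0, 2**31 - 1))


def _load_image_model(ckpt: Checkpoint, tc: TrainConfig, config: ExperimentConfig, fold: int):
    seed = _model_seed(config, fold)
    model = build_two_branch_model(
        TinyConvNet(tc.input_size, rng=np.random.default_rng(seed)), None,
        n_classes=tc.num_classes, seed=seed)
    model.load_state(ckpt.state)
    return model


def _load_meta_model(ckpt: Checkpoint, tc: TrainConfig, config: ExperimentConfig, fold: int):
    seed = _model_seed(config, fold)
    model = build_two_branch_model(
        TinyConvNet(tc.input_size, rng=np.random.default_rng(seed)),
        config.meta_train.meta_spec, n_classes=tc.num_classes, seed=seed)
    model.load_state(ckpt.state)
    return model


def run_pipeline(config: ExperimentConfig, out_dir: Optional[Path] = None) -> PipelineArtifacts:
    """Execute all stages and write a selection report.

    Stages: synthetic dataset generation, preprocessing, per-configuration
    cross-validated training (image stage, plus the frozen-CNN metadata
    stage when ``use_meta``), multi-view TTA prediction on the held-out
    folds, exhaustive ensemble subset search on the best checkpoints, and
    best+last pooling of the selected subset.
    """
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    dataset = gen_lesion_dataset(config.dataset)
    dataset = LesionDataset(
        records=[preprocess(r, PreprocessParams()) for r in dataset.records],
        meta=dataset.meta, labels=dataset.labels, lesion_ids=dataset.lesion_ids,
    )
    split = grouped_kfold(dataset.lesion_ids, n_folds=config.n_folds, seed=config.seed)

    fold_results: dict[str, list[FoldResult]] = {}
    for cspec in config.configurations:
        tc = replace(config.train, strategy=cspec.strategy(), seed=config.train.seed)
        logger.info("training configuration %s", cspec.name)
        results = train_cnn(dataset, split, tc)
        if config.use_meta:
            results = train_meta(dataset, split, results, tc, config.meta_train)
        fold_results[cspec.name] = results

    best_tensor = _predict_tensor(dataset, split, config, fold_results, "best")
    last_tensor = _predict_tensor(dataset, split, config, fold_results, "last")
    selection = exhaustive_subset_search(best_tensor, max_configs=config.max_configs)
    final = pool_best_last(selection, best_tensor, last_tensor)
    final_s = mean_sensitivity(best_tensor.pooled_labels(), np.concatenate(final))

    full_avg = ensemble_average(best_tensor, range(best_tensor.n_configs))
    report = {
        **_stamp(config),
        "configurations": [c.name for c in config.configurations],
        "selection": selection.to_json_dict(),
        "selected_names": [config.configurations[i].name for i in selection.subset],
        "ensemble_average_S": mean_sensitivity(
            best_tensor.pooled_labels(), np.concatenate(full_avg)),
        "ensemble_optimal_S": selection.mean_sensitivity,
        "final_best_last_S": final_s,
        "per_config_S": {
            c.name: mean_sensitivity(best_tensor.pooled_labels(),
                                     np.concatenate(ensemble_average(best_tensor, [i])))
            for i, c in enumerate(config.configurations)
        },
    }
    with open(out / "selection.json", "w") as fh:
        json.dump(report, fh, indent=2)
    preds = {}
    offset_ids = []
    for fold in range(split.n_folds):
        va = split.val_indices(fold, dataset.lesion_ids)
        offset_ids.extend([dataset.records[i].image_id for i in va])
    flat = np.concatenate(final)
    for image_id, row in zip(offset_ids, flat):
        preds[image_id] = row
    write_submission(preds, out / "submission.csv")
    return PipelineArtifacts(dataset, split, fold_results, best_tensor, last_tensor,
                             selection, final, report)
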