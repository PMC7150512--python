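import numpy as np
import pytest

from dermpipe import (
    AugmentParams,
    InputStrategy,
    SyntheticDatasetSpec,
    SyntheticImageSpec,
    TrainConfig,
    gen_dermoscopy_image,
    gen_lesion_dataset,
)

# light augmentation (flips, photometric, cutout) so desk-scale runs stay fast
FAST_AUG = AugmentParams(rotation_deg=0, shear_deg=0, scale_range=(1.0, 1.0))
SMOKE_CFG = TrainConfig(epochs=10, eval_period=5, base_lr=1e-3, batch_size=32, seed=0,
                        input_size=(64, 64),
                        strategy=InputStrategy("same_sized", (64, 64)), augment=FAST_AUG)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_disk_spec(rng, width=600, height=450, margin=0.0):
    """A FOV-disk image spec with the disk fully inside the frame."""
    r = float(rng.uniform(0.25, 0.45) * min(width, height))
    cx = float(rng.uniform(r + margin, width - r - margin))
    cy = float(rng.uniform(r + margin, height - r - margin))
    return SyntheticImageSpec(
        width=width, height=height, fov_center=(cx, cy), fov_radius=r,
        lesion_class=int(rng.integers(0, 9)), seed=int(rng.integers(0, 2**31 - 1)),
    )


@pytest.fixture
def disk_image(rng):
    spec = random_disk_spec(rng)
    rec, box = gen_dermoscopy_image(spec)
    return rec, box, spec


@pytest.fixture(scope="session")
def separable_dataset():
    """450 images (150 lesions x 3) whose class is recoverable from the image."""
    spec = SyntheticDatasetSpec(n_lesions=150, images_per_lesion=3, seed=1,
                                width=72, height=72)
    return gen_lesion_dataset(spec)


@pytest.fixture(scope="session")
def smoke_trained_fold(separable_dataset):
    """One CV fold of stage-1 training on the separable 450-image dataset."""
    from dermpipe import grouped_kfold
    from dermpipe.training import train_fold_cnn

    ds = separable_dataset
    split = grouped_kfold(ds.lesion_ids, n_folds=5, seed=0)
    tr = split.train_indices(0, ds.lesion_ids)
    va = split.val_indices(0, ds.lesion_ids)
    result = train_fold_cnn(ds, tr, va, SMOKE_CFG, fold=0)
    return ds, tr, va, result


@pytest.fixture(scope="session")
def meta_signal_dataset():
    """Dataset whose class is determined by the metadata, not the pixels."""
    spec = SyntheticDatasetSpec(n_lesions=120, images_per_lesion=2, seed=2,
                                width=72, height=72, class_signal="meta",
                                metadata_missing_rates=(0.0, 0.0, 0.0))
    return gen_lesion_dataset(spec)


@pytest.fixture(scope="session")
def meta_stage_results(meta_signal_dataset):
    """Image-only vs frozen-CNN+metadata training on the metadata-driven dataset."""
    from dermpipe import MetaTrainConfig, grouped_kfold
    from dermpipe.nn import MetaBranchSpec
    from dermpipe.training import train_fold_cnn, train_fold_meta

    ds = meta_signal_dataset
    split = grouped_kfold(ds.lesion_ids, n_folds=3, seed=0)
    tr = split.train_indices(0, ds.lesion_ids)
    va = split.val_indices(0, ds.lesion_ids)
    cfg = TrainConfig(epochs=4, eval_period=2, base_lr=1e-3, batch_size=32, seed=0,
                      input_size=(64, 64),
                      strategy=InputStrategy("same_sized", (64, 64)), augment=FAST_AUG)
    image_only = train_fold_cnn(ds, tr, va, cfg, fold=0)
    mcfg = MetaTrainConfig(epochs=12, lr=1e-3, batch_size=20, eval_period=4,
                           meta_spec=MetaBranchSpec(fusion_width=256))
    meta = train_fold_meta(ds, tr, va, image_only.best, cfg, mcfg, fold=0)
    return image_only, meta
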