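"""Backbone contract, tiny CNN backbone and the two-branch classifier.

The classifier has the structure used for dermoscopy + patient metadata:
a CNN backbone ending in global average pooling yields a feature vector; a
dense branch maps the 11-dimensional metadata vector through two 256-unit
layers (batch-norm, ReLU, dropout 0.4); the two are concatenated and pass
through one fusion layer (1024 units baseline, scalable) before the 9-way
classification layer.  In image-only mode the classification layer sits
directly on the pooled CNN features.

Any backbone satisfying the small contract below can be plugged in; the
package ships :class:`TinyConvNet`, a three-block CNN sized for desk-scale
experiments on synthetic data.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .layers import (
    BatchNorm1d,
    BatchNorm2d,
    Conv2d,
    Dropout,
    GlobalAvgPool,
    Layer,
    Linear,
    Param,
    ReLU,
    Sequential,
)


class Backbone(Layer):
    """Contract: maps ``(N, 3, H, W)`` to pooled features ``(N, feature_width)``."""

    feature_width: int
    input_size: tuple[int, int]


class TinyConvNet(Backbone):
    """Three conv blocks (stride 2, batch-norm, ReLU) + global average pool."""

    def __init__(self, input_size: tuple[int, int] = (64, 64),
                 widths: tuple[int, int, int] = (16, 32, 64),
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.input_size = tuple(input_size)
        self.feature_width = widths[-1]
        blocks: list[Layer] = []
        cin = 3
        for cout in widths:
            blocks += [Conv2d(cin, cout, k=3, stride=2, pad=1, rng=rng),
                       BatchNorm2d(cout), ReLU()]
            cin = cout
        blocks.append(GlobalAvgPool())
        self.net = Sequential(*blocks)

    def forward(self, x, train=False):
        return self.net.forward(x, train=train)

    def backward(self, gout):
        return self.net.backward(gout)

    def params(self):
        return self.net.params()

    def state_arrays(self):
        return self.net.state_arrays()


@dataclass(frozen=True)
class MetaBranchSpec:
    """Dense metadata branch and fusion-layer geometry."""

    meta_dim: int = 11
    hidden: tuple[int, ...] = (256, 256)
    dropout: float = 0.4
    fusion_width: int = 1024

    def __post_init__(self) -> None:
        if any(wd <= 0 for wd in self.hidden) or self.fusion_width <= 0:
            raise ValueError("layer widths must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


class TwoBranchClassifier:
    """Image (+ optional metadata) classifier over ``n_classes`` outputs."""

    def __init__(self, backbone: Backbone, meta_spec: MetaBranchSpec | None = None,
                 n_classes: int = 9, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        if backbone.feature_width <= 0:
            raise ValueError("backbone must declare a positive feature width")
        self.backbone = backbone
        self.meta_spec = meta_spec
        self.n_classes = n_classes
        self.backbone_frozen = False
        if meta_spec is None:
            self.meta_branch = None
            self.fusion = None
            self.classifier = Linear(backbone.feature_width, n_classes, rng=rng)
        else:
            layers: list[Layer] = []
            din = meta_spec.meta_dim
            for width in meta_spec.hidden:
                layers += [Linear(din, width, rng=rng), BatchNorm1d(width), ReLU(),
                           Dropout(meta_spec.dropout, rng)]
                din = width
            self.meta_branch = Sequential(*layers)
            concat_width = backbone.feature_width + din
            self.fusion = Sequential(
                Linear(concat_width, meta_spec.fusion_width, rng=rng),
                BatchNorm1d(meta_spec.fusion_width), ReLU(),
                Dropout(meta_spec.dropout, rng),
            )
            self.classifier = Linear(meta_spec.fusion_width, n_classes, rng=rng)
        self._cache_fw = None

    @property
    def uses_meta(self) -> bool:
        return self.meta_branch is not None

    def forward(self, x: np.ndarray, meta: np.ndarray | None = None,
                train: bool = False) -> np.ndarray:
        if self.uses_meta:
            if meta is None:
                raise ValueError("this model requires a metadata vector")
            feats = self.backbone.forward(x, train=train and not self.backbone_frozen)
            mfeats = self.meta_branch.forward(meta, train=train)
            z = np.concatenate([feats, mfeats], axis=1)
            self._cache_fw = feats.shape[1]
            h = self.fusion.forward(z, train=train)
            return self.classifier.forward(h, train=train)
        if meta is not None:
            raise ValueError("metadata passed to an image-only model")
        feats = self.backbone.forward(x, train=train)
        return self.classifier.forward(feats, train=train)

    def backward(self, glogits: np.ndarray) -> None:
        g = self.classifier.backward(glogits)
        if self.uses_meta:
            g = self.fusion.backward(g)
            fw = self._cache_fw
            gfeat, gmeta = g[:, :fw], g[:, fw:]
            self.meta_branch.backward(gmeta)
            if not self.backbone_frozen:
                self.backbone.backward(gfeat)
        else:
            if not self.backbone_frozen:
                self.backbone.backward(g)

    def freeze_backbone(self) -> None:
        self.backbone_frozen = True
        for p in self.backbone.params():
            p.trainable = False

    # -- parameters and persistence -------------------------------------
    def params(self) -> list[Param]:
        out = list(self.backbone.params())
        if self.uses_meta:
            out += self.meta_branch.params() + self.fusion.params()
        out += self.classifier.params()
        return out

    def trainable_params(self) -> list[Param]:
        return [p for p in self.params() if p.trainable]

    def state_arrays(self) -> list[np.ndarray]:
        out = list(self.backbone.state_arrays())
        if self.uses_meta:
            out += self.meta_branch.state_arrays() + self.fusion.state_arrays()
        out += self.classifier.state_arrays()
        return out

    def get_state(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def load_state(self, state: list[np.ndarray]) -> None:
        arrays = self.state_arrays()
        if len(arrays) != len(state):
            raise ValueError("state length mismatch")
        for dst, src in zip(arrays, state):
            if dst.shape != np.asarray(src).shape:
                raise ValueError("state shape mismatch")
            dst[...] = src

    def backbone_hash(self) -> str:
        """Digest of all backbone arrays — used to verify the freeze contract."""
        h = hashlib.sha256()
        for a in self.backbone.state_arrays():
            h.update(np.ascontiguousarray(a).tobytes())
        return h.hexdigest()


def build_two_branch_model(backbone: Backbone, meta_spec: MetaBranchSpec | None = None,
                           n_classes: int = 9, seed: int = 0) -> TwoBranchClassifier:
    """Construct the classifier with reproducible initialization."""
    rng = np.random.default_rng(seed)
    return TwoBranchClassifier(backbone, meta_spec, n_classes=n_classes, rng=rng)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)
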