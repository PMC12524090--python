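"""Classifier architectures: the custom CNN branch, the transfer branch with a
pluggable feature-extractor backbone, the feature-fusion model, and the
"reduce LR on multiple accuracies" scheduling callback.

All classifiers satisfy one contract: ``fit`` on (images, labels) with an
optional validation set, ``predict_proba`` returning rows that sum to one,
``extract_features`` returning an ``(n, feature_dim)`` matrix.  The custom
branch takes 168×168×1 input (four 5×5/4×4 conv blocks, 3×3 pooling, dense
512); the transfer branch takes 224×224×3 and applies global average pooling
→ dropout → dense 128 over any backbone feature map; the fusion model
concatenates the two branch feature vectors (128 + 512 = 640 for the
full-size branches) under a dense-256 head.  Tiny variants with the same
contract exist for fast experimentation on small images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .data import DatasetSpec
from .pseudolabel import ProbabilityMatrix

__all__ = [
    "TrainConfig",
    "LRCallbackConfig",
    "ReduceLROnMultipleAccuracies",
    "lr_callback_step",
    "NetworkClassifier",
    "FusionClassifier",
    "build_custom_cnn",
    "build_transfer_branch",
    "build_tiny_backbone",
    "build_fusion_model",
]


@dataclass(frozen=True)
class LRCallbackConfig:
    """Reduce-LR-on-multiple-accuracies policy: each time validation accuracy
    first exceeds one of the thresholds, multiply the learning rate by
    ``factor`` (never below ``min_lr``); each threshold fires at most once."""

    accuracy_thresholds: tuple[float, ...] = (0.96, 0.99, 0.9935)
    factor: float = 0.75
    min_lr: float = 1e-4

    def __post_init__(self) -> None:
        t = tuple(self.accuracy_thresholds)
        if any(not (0.0 < x < 1.0) for x in t):
            raise ValueError("thresholds must lie in (0, 1)")
        if any(t[i] >= t[i + 1] for i in range(len(t) - 1)):
            raise ValueError("thresholds must be strictly increasing")
        if not (0.0 < self.factor < 1.0):
            raise ValueError("factor must be in (0, 1)")
        object.__setattr__(self, "accuracy_thresholds", t)


def lr_callback_step(
    state: tuple[float, frozenset[int]], val_accuracy: float, config: LRCallbackConfig
) -> tuple[float, frozenset[int]]:
    """Pure-functional step of the LR policy.

    ``state`` is ``(current_lr, consumed_threshold_indices)``; every
    not-yet-consumed threshold strictly below ``val_accuracy`` fires once,
    multiplying the rate by ``factor`` and clamping at ``min_lr``.
    """
    lr, consumed = state
    for i, threshold in enumerate(config.accuracy_thresholds):
        if i not in consumed and val_accuracy > threshold:
            lr = max(lr * config.factor, config.min_lr)
            consumed = consumed | {i}
    return lr, frozenset(consumed)


class ReduceLROnMultipleAccuracies:
    """Stateful wrapper around :func:`lr_callback_step` bound to an optimizer."""

    def __init__(self, optimizer: nn.Adam, config: LRCallbackConfig):
        self.optimizer = optimizer
        self.config = config
        self._consumed: frozenset[int] = frozenset()

    def on_epoch_end(self, val_accuracy: float) -> None:
        lr, self._consumed = lr_callback_step(
            (self.optimizer.lr, self._consumed), val_accuracy, self.config
        )
        self.optimizer.lr = lr


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings; ``learning_rate=None`` keeps the architecture's
    own default (0.001 Adam for the custom branch, 1e-4 Adamax for the
    transfer branch, 1e-4 Adam for the fusion head)."""

    epochs: int = 50
    batch_size: int = 32
    learning_rate: "float | None" = None
    lr_callback: "LRCallbackConfig | None" = field(default_factory=LRCallbackConfig)
    seed: int = 0
    checkpoint_best: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.learning_rate is not None and self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass(frozen=True)
class OptimizerSpec:
    name: str  # "adam" | "adamax"
    lr: float
    beta1: float
    beta2: float

    def build(self, lr_override: "float | None" = None) -> nn.Adam:
        lr = self.lr if lr_override is None else lr_override
        cls = nn.Adamax if self.name == "adamax" else nn.Adam
        return cls(lr, beta1=self.beta1, beta2=self.beta2)


class NetworkClassifier:
    """The classifier contract realised by a sequential :class:`~pseudofuse.nn.Network`.

    ``trainable_mask`` (parallel to the layer list) freezes parameter blocks,
    which is how the transfer branch keeps its backbone fixed.  Inference is
    deterministic (dropout only acts during fitting).
    """

    def __init__(
        self,
        network: nn.Network,
        optimizer_spec: OptimizerSpec,
        feature_dim: int,
        input_shape: tuple[int, int, int],
        trainable_mask: "list[bool] | None" = None,
    ):
        self.network = network
        self.optimizer_spec = optimizer_spec
        self.feature_dim = feature_dim
        self.input_shape = input_shape
        self.trainable_mask = trainable_mask

    def _check(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=np.float64)
        if images.shape[1:] != self.input_shape:
            raise ValueError(
                f"expected images of shape {self.input_shape}, got {images.shape[1:]}"
            )
        return images

    def fit(
        self,
        images: np.ndarray,
        labels: np.ndarray,
        val_images: "np.ndarray | None" = None,
        val_labels: "np.ndarray | None" = None,
        config: "TrainConfig | None" = None,
        sample_weights: "np.ndarray | None" = None,
        epoch_transform=None,
    ) -> dict:
        """Minibatch training with optional best-checkpoint restore.

        Returns a history dict with per-epoch ``loss``, ``val_accuracy`` and
        ``lr``.  Calling ``fit`` again continues from the current weights
        (warm start) with a fresh optimizer state.  ``epoch_transform``, if
        given, is applied to the full image stack at the start of every epoch
        (stochastic augmentation + normalisation); the validation images are
        used exactly as passed.
        """
        config = config or TrainConfig()
        images = self._check(images)
        labels = np.asarray(labels, dtype=np.int64)
        weights_all = None if sample_weights is None else np.asarray(sample_weights, float)
        rng = np.random.default_rng(config.seed)
        optimizer = self.optimizer_spec.build(config.learning_rate)
        callback = (
            ReduceLROnMultipleAccuracies(optimizer, config.lr_callback)
            if config.lr_callback is not None
            else None
        )
        has_val = val_images is not None and val_labels is not None and len(val_images) > 0
        history: dict = {"loss": [], "val_accuracy": [], "lr": []}
        best_acc, best_weights = -1.0, None
        for _epoch in range(config.epochs):
            epoch_images = images if epoch_transform is None else epoch_transform(images)
            order = rng.permutation(len(images))
            losses = []
            for start in range(0, len(images), config.batch_size):
                idx = order[start : start + config.batch_size]
                losses.append(
                    self.network.train_batch(
                        epoch_images[idx],
                        labels[idx],
                        optimizer,
                        self.trainable_mask,
                        None if weights_all is None else weights_all[idx],
                    )
                )
            history["loss"].append(float(np.mean(losses)))
            if has_val:
                preds = self.predict_proba(val_images).argmax(axis=1)
                acc = float(np.mean(preds == np.asarray(val_labels)))
                history["val_accuracy"].append(acc)
                if callback is not None:
                    callback.on_epoch_end(acc)
                if config.checkpoint_best and acc > best_acc:
                    best_acc, best_weights = acc, self.network.get_weights()
            history["lr"].append(optimizer.lr)
        if best_weights is not None:
            self.network.set_weights(best_weights)
        return history

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return self.network.predict_proba(self._check(images))

    def score_pool(self, images: np.ndarray, sample_ids) -> ProbabilityMatrix:
        return ProbabilityMatrix(tuple(sample_ids), self.predict_proba(images))

    def extract_features(self, images: np.ndarray) -> np.ndarray:
        feats = self.network.features(self._check(images))
        if feats.shape[1] != self.feature_dim:
            raise AssertionError("feature width does not match declared feature_dim")
        return feats


def build_custom_cnn(spec: DatasetSpec, tiny: bool = False, seed: int = 0) -> NetworkClassifier:
    """Grayscale CNN branch.

    Full variant (168×168×1): conv(64, 5×5) → pool(3×3) → conv(64, 5×5) →
    pool → conv(128, 4×4) → pool → conv(128, 4×4) → pool → flatten →
    dense(512, ReLU) → softmax head; Adam with lr 0.001, β1 0.85, β2 0.9925;
    feature_dim 512.  Tiny variant (≥32×32): two conv blocks (8, 16 filters,
    3×3), dense 32; same contract and optimizer family; feature_dim 32.
    """
    if spec.channels != 1:
        raise ValueError("custom CNN expects single-channel input")
    rng = np.random.default_rng(seed)
    h, w = spec.image_height, spec.image_width
    if tiny:
        if h < 32 or w < 32:
            raise ValueError("tiny custom CNN needs input of at least 32×32")
        blocks = [(8, 3), (16, 3)]
        pool, dense_units = 2, 32
    else:
        if (h, w) != (168, 168):
            raise ValueError("full custom CNN expects 168×168 input")
        blocks = [(64, 5), (64, 5), (128, 4), (128, 4)]
        pool, dense_units = 3, 512

    layers: list[nn.Layer] = []
    ch, fh, fw = spec.channels, h, w
    for filters, k in blocks:
        layers += [nn.Conv2D(ch, filters, k, rng), nn.ReLU()]
        fh, fw = fh - k + 1, fw - k + 1
        if fh >= pool and fw >= pool:  # pooling skipped once the map is tiny
            layers.append(nn.MaxPool2D(pool))
            fh, fw = fh // pool, fw // pool
        ch = filters
    layers.append(nn.Flatten())
    layers.append(nn.Dense(fh * fw * ch, dense_units, rng))
    layers.append(nn.ReLU())
    feature_index = len(layers) - 1
    layers.append(nn.Dense(dense_units, spec.n_classes, rng))
    network = nn.Network(layers, feature_index)
    opt = OptimizerSpec("adam", lr=0.001, beta1=0.85, beta2=0.9925)
    return NetworkClassifier(network, opt, dense_units, spec.shape)


def build_tiny_backbone(channels: int, seed: int = 0) -> list[nn.Layer]:
    """Small three-block convolutional feature extractor (8/16/32 filters)
    used as the default desk-scale backbone of the transfer branch."""
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    ch = channels
    for filters in (8, 16, 32):
        layers += [nn.Conv2D(ch, filters, 3, rng), nn.ReLU(), nn.MaxPool2D(2)]
        ch = filters
    return layers


def build_transfer_branch(
    spec: DatasetSpec,
    backbone: "list[nn.Layer] | None" = None,
    freeze_backbone: bool = True,
    seed: int = 0,
) -> NetworkClassifier:
    """RGB transfer branch: backbone feature map → global average pooling →
    dropout 0.5 → dense(128, ReLU) → dropout 0.5 → softmax; Adamax, lr 1e-4;
    feature_dim 128.

    ``backbone`` is any list of layers mapping the input to a 4-D feature
    map; by default a small randomly-initialised CNN
    (:func:`build_tiny_backbone`).  With ``freeze_backbone`` (default) only
    the head trains.
    """
    if spec.channels != 3:
        raise ValueError("transfer branch expects 3-channel input")
    rng = np.random.default_rng(seed + 1)
    backbone = backbone if backbone is not None else build_tiny_backbone(3, seed)
    probe = np.zeros((1, *spec.shape))
    fmap = probe
    for layer in backbone:
        fmap = layer.forward(fmap, train=False)
    if fmap.ndim != 4:
        raise ValueError("backbone must output a 4-D feature map (n, h, w, c)")
    backbone_channels = fmap.shape[-1]

    head: list[nn.Layer] = [
        nn.GlobalAvgPool(),
        nn.Dropout(0.5, rng),
        nn.Dense(backbone_channels, 128, rng),
        nn.ReLU(),
        nn.Dropout(0.5, rng),
    ]
    layers = list(backbone) + head
    feature_index = len(layers) - 2  # the ReLU after dense-128
    layers.append(nn.Dense(128, spec.n_classes, rng))
    network = nn.Network(layers, feature_index)
    mask = [not freeze_backbone] * len(backbone) + [True] * (len(head) + 1)
    opt = OptimizerSpec("adamax", lr=1e-4, beta1=0.9, beta2=0.999)
    return NetworkClassifier(network, opt, 128, spec.shape, trainable_mask=mask)


class FusionClassifier:
    """Feature-level fusion of two branch classifiers.

    Branch feature vectors are concatenated (RGB branch first, matching the
    128 + 512 = 640 layout of the full-size pair) and classified by a
    dropout(0.5) → dense(``head_units``, ReLU) → dropout(0.3) → softmax head
    trained with Adam at lr 1e-4.  Branches stay frozen while the head
    trains; ``feature_dim`` is the fused width.
    """

    def __init__(
        self,
        branch_gray: NetworkClassifier,
        branch_rgb: NetworkClassifier,
        n_classes: int,
        head_units: int = 256,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed + 2)
        self.branch_gray = branch_gray
        self.branch_rgb = branch_rgb
        self.feature_dim = branch_rgb.feature_dim + branch_gray.feature_dim
        layers: list[nn.Layer] = [
            nn.Dropout(0.5, rng),
            nn.Dense(self.feature_dim, head_units, rng),
            nn.ReLU(),
            nn.Dropout(0.3, rng),
        ]
        feature_index = len(layers) - 2
        layers.append(nn.Dense(head_units, n_classes, rng))
        self.head = nn.Network(layers, feature_index)
        self.optimizer_spec = OptimizerSpec("adam", lr=1e-4, beta1=0.9, beta2=0.999)

    def _fused(self, gray_images: np.ndarray, rgb_images: np.ndarray) -> np.ndarray:
        if len(gray_images) != len(rgb_images):
            raise ValueError("paired views must contain the same samples in the same order")
        return np.concatenate(
            [
                self.branch_rgb.extract_features(rgb_images),
                self.branch_gray.extract_features(gray_images),
            ],
            axis=1,
        )

    def extract_features(self, gray_images: np.ndarray, rgb_images: np.ndarray) -> np.ndarray:
        return self._fused(gray_images, rgb_images)

    def fit(
        self,
        gray_images: np.ndarray,
        rgb_images: np.ndarray,
        labels: np.ndarray,
        val: "tuple[np.ndarray, np.ndarray, np.ndarray] | None" = None,
        config: "TrainConfig | None" = None,
    ) -> dict:
        config = config or TrainConfig()
        feats = self._fused(gray_images, rgb_images)
        labels = np.asarray(labels, dtype=np.int64)
        rng = np.random.default_rng(config.seed)
        optimizer = self.optimizer_spec.build(config.learning_rate)
        callback = (
            ReduceLROnMultipleAccuracies(optimizer, config.lr_callback)
            if config.lr_callback is not None
            else None
        )
        val_feats = val_labels = None
        if val is not None:
            val_feats = self._fused(val[0], val[1])
            val_labels = np.asarray(val[2])
        history: dict = {"loss": [], "val_accuracy": [], "lr": []}
        best_acc, best_weights = -1.0, None
        for _epoch in range(config.epochs):
            order = rng.permutation(len(feats))
            losses = []
            for start in range(0, len(feats), config.batch_size):
                idx = order[start : start + config.batch_size]
                losses.append(self.head.train_batch(feats[idx], labels[idx], optimizer))
            history["loss"].append(float(np.mean(losses)))
            if val_feats is not None and len(val_feats):
                acc = float(
                    np.mean(nn.softmax(self.head.logits(val_feats)).argmax(axis=1) == val_labels)
                )
                history["val_accuracy"].append(acc)
                if callback is not None:
                    callback.on_epoch_end(acc)
                if config.checkpoint_best and acc > best_acc:
                    best_acc, best_weights = acc, self.head.get_weights()
            history["lr"].append(optimizer.lr)
        if best_weights is not None:
            self.head.set_weights(best_weights)
        return history

    def predict_proba(self, gray_images: np.ndarray, rgb_images: np.ndarray) -> np.ndarray:
        return self.head.predict_proba(self._fused(gray_images, rgb_images))


def build_fusion_model(
    branch_gray: NetworkClassifier,
    branch_rgb: NetworkClassifier,
    n_classes: int,
    head_units: int = 256,
    seed: int = 0,
) -> FusionClassifier:
    """Assemble the fusion classifier over two trained branches; the fused
    width is the sum of the branch feature dims (640 for the full pair)."""
    return FusionClassifier(branch_gray, branch_rgb, n_classes, head_units, seed)
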