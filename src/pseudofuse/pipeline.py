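"""Experiment orchestration: supervised baselines, semi-supervised runs for a
single model and for the consensus/fusion pair, and grids over labelled
fractions.

A run follows the self-training recipe: supervised warm-up on the labelled
pool, then up to T pseudo-labelling iterations — score the *remaining*
unlabelled pool on clean (normalisation-only) images, accept samples whose
confidence meets the iteration's threshold, merge them into the training set
(pseudo-labelled samples weighted by λ), retrain, and carry the rejected
samples into the next iteration.  In consensus/fusion mode two branches vote
on each pseudo-label, and the final classifier is a feature-fusion head
trained on the merged set.  The test set never participates in any of this
(asserted by id disjointness), and on synthetic data the hidden truth of the
unlabelled pool yields a pseudo-label precision figure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .backbones import (
    FusionClassifier,
    NetworkClassifier,
    TrainConfig,
    build_custom_cnn,
    build_fusion_model,
    build_transfer_branch,
)
from .data import DatasetSpec, LabeledDataset, SplitResult, UnlabeledPool, stratified_split
from .metrics import ClassReport, classification_report
from .phantoms import PhantomConfig, generate_phantoms
from .preprocessing import AugmentConfig, make_eval_pipeline, make_train_pipeline
from .pseudolabel import (
    IterationLedger,
    LossConfig,
    PseudoLabelRecord,
    ProbabilityMatrix,
    ThresholdSchedule,
    confidence_filter,
    consensus_vote,
)

__all__ = ["RunConfig", "RunReport", "run_supervised_baseline", "run_ssl", "run_grid", "phantom_benchmark"]

MODES = ("supervised_only", "ssl_single", "ssl_consensus_fusion")


@dataclass(frozen=True)
class RunConfig:
    """Settings of one experiment cell."""

    mode: str = "ssl_single"
    labelled_fraction: float = 0.1
    schedule: ThresholdSchedule = field(default_factory=ThresholdSchedule)
    loss: LossConfig = field(default_factory=LossConfig)
    train: TrainConfig = field(default_factory=lambda: TrainConfig(epochs=20))
    epochs_per_ssl_iteration: int = 10
    validation_fraction: float = 0.1
    augment: Optional[AugmentConfig] = None
    tiny: bool = True
    seed: int = 0
    disagreement_policy: str = "reject"
    refresh_branches: bool = True
    retrain_from_scratch: bool = False

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if not (0.0 < self.labelled_fraction <= 1.0):
            raise ValueError("labelled_fraction must be in (0, 1]")
        if self.epochs_per_ssl_iteration < 1:
            raise ValueError("epochs_per_ssl_iteration must be >= 1")
        if not (0.0 <= self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must be in [0, 1)")

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "labelled_fraction": self.labelled_fraction,
            "thresholds": list(self.schedule.thresholds),
            "lambda": self.loss.lam,
            "ramp_epochs": self.loss.ramp_epochs,
            "epochs": self.train.epochs,
            "batch_size": self.train.batch_size,
            "epochs_per_ssl_iteration": self.epochs_per_ssl_iteration,
            "validation_fraction": self.validation_fraction,
            "tiny": self.tiny,
            "seed": self.seed,
            "disagreement_policy": self.disagreement_policy,
        }


@dataclass
class RunReport:
    mode: str
    test_accuracy: float
    report: ClassReport
    ledger: IterationLedger
    pseudo_label_precision: Optional[float]
    n_labelled: int
    n_merged: int
    config: dict
    seed: int

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "test_accuracy": self.test_accuracy,
            "metrics": self.report.to_dict(),
            "ledger": self.ledger.to_records(),
            "pseudo_label_precision": self.pseudo_label_precision,
            "n_labelled": self.n_labelled,
            "n_merged": self.n_merged,
            "config": self.config,
            "seed": self.seed,
        }


def _spec_of(data: LabeledDataset) -> DatasetSpec:
    h, w, c = data.images.shape[1:]
    names = tuple(f"class_{i}" for i in range(data.n_classes))
    return DatasetSpec(names, h, w, c)


def _check_disjoint(train_ids, test: LabeledDataset) -> None:
    overlap = set(train_ids) & set(test.sample_ids)
    if overlap:
        raise ValueError(f"test set overlaps training data: {sorted(overlap)[:3]} ...")


def _carve_validation(
    labelled: LabeledDataset, fraction: float, seed: int
) -> tuple[LabeledDataset, "np.ndarray | None", "np.ndarray | None"]:
    """Split off a stratified validation share of the labelled set."""
    if fraction <= 0 or len(labelled) < 2 * labelled.n_classes:
        return labelled, None, None
    sub = stratified_split(labelled, 1.0 - fraction, seed + 101)
    val_labels = np.array([sub.hidden_labels[s] for s in sub.unlabelled.sample_ids])
    if len(val_labels) == 0:
        return labelled, None, None
    return sub.labelled, sub.unlabelled.images, val_labels


def _transforms(config: RunConfig):
    eval_tf = make_eval_pipeline()
    if config.augment is None:
        return eval_tf, None
    return eval_tf, make_train_pipeline(config.augment, config.seed + 777)


def _fit_single(
    model: NetworkClassifier,
    images: np.ndarray,
    labels: np.ndarray,
    val: tuple,
    config: RunConfig,
    epochs: int,
    sample_weights: "np.ndarray | None" = None,
) -> None:
    eval_tf, train_tf = _transforms(config)
    val_images, val_labels = val
    train_cfg = TrainConfig(
        epochs=epochs,
        batch_size=config.train.batch_size,
        learning_rate=config.train.learning_rate,
        lr_callback=config.train.lr_callback,
        seed=config.seed,
        checkpoint_best=config.train.checkpoint_best and val_images is not None,
    )
    if train_tf is None:
        model.fit(
            eval_tf(images),
            labels,
            None if val_images is None else eval_tf(val_images),
            val_labels,
            train_cfg,
            sample_weights=sample_weights,
        )
    else:
        model.fit(
            images,
            labels,
            None if val_images is None else eval_tf(val_images),
            val_labels,
            train_cfg,
            sample_weights=sample_weights,
            epoch_transform=train_tf,
        )


def _evaluate_single(model: NetworkClassifier, test: LabeledDataset) -> tuple[float, ClassReport]:
    eval_tf = make_eval_pipeline()
    preds = model.predict_proba(eval_tf(test.images)).argmax(axis=1)
    report = classification_report(test.labels, preds, test.n_classes)
    return report.accuracy, report


def run_supervised_baseline(split: SplitResult, test: LabeledDataset, config: RunConfig) -> RunReport:
    """Train on the labelled pool only and evaluate on the test set."""
    if len(split.labelled) == 0:
        raise ValueError("labelled set is empty")
    _check_disjoint(split.labelled.sample_ids, test)
    spec = _spec_of(split.labelled)
    train_set, val_images, val_labels = _carve_validation(
        split.labelled, config.validation_fraction, config.seed
    )
    model = build_custom_cnn(spec, tiny=config.tiny, seed=config.seed)
    _fit_single(
        model, train_set.images, train_set.labels, (val_images, val_labels), config,
        config.train.epochs,
    )
    accuracy, report = _evaluate_single(model, test)
    return RunReport(
        mode="supervised_only",
        test_accuracy=accuracy,
        report=report,
        ledger=IterationLedger(),
        pseudo_label_precision=None,
        n_labelled=len(split.labelled),
        n_merged=len(split.labelled),
        config=config.to_dict(),
        seed=config.seed,
    )


def _precision_against_hidden(
    records: list[PseudoLabelRecord], hidden: dict[str, int]
) -> Optional[float]:
    known = [r for r in records if r.sample_id in hidden]
    if not known:
        return None
    return float(np.mean([r.label == hidden[r.sample_id] for r in known]))


def _lambda_weights(n_real: int, records: list[PseudoLabelRecord], config: RunConfig) -> np.ndarray:
    lam = config.loss.lam
    if config.loss.ramp_epochs > 0:
        # one merged retraining counts as one ramp step per accepted iteration
        lam = lam * min(1.0, max(r.iteration for r in records) / config.loss.ramp_epochs)
    return np.concatenate([np.ones(n_real), np.full(len(records), lam)])


def _run_ssl_single(split: SplitResult, test: LabeledDataset, config: RunConfig) -> RunReport:
    spec = _spec_of(split.labelled)
    eval_tf, _ = _transforms(config)
    train_set, val_images, val_labels = _carve_validation(
        split.labelled, config.validation_fraction, config.seed
    )
    model = build_custom_cnn(spec, tiny=config.tiny, seed=config.seed)
    _fit_single(
        model, train_set.images, train_set.labels, (val_images, val_labels), config,
        config.train.epochs,
    )
    initial_weights = model.network.get_weights() if config.retrain_from_scratch else None

    pool = split.unlabelled
    id_to_index = {sid: i for i, sid in enumerate(pool.sample_ids)}
    remaining = list(pool.sample_ids)
    merged: list[PseudoLabelRecord] = []
    ledger = IterationLedger()
    for t, tau in enumerate(config.schedule.thresholds, start=1):
        if not remaining:
            break
        idx = np.array([id_to_index[s] for s in remaining])
        probs = ProbabilityMatrix(
            tuple(remaining), model.predict_proba(eval_tf(pool.images[idx]))
        )
        accepted, rejected = confidence_filter(probs, tau, iteration=t)
        ledger.add(t, tau, len(accepted), len(rejected))
        merged.extend(accepted)
        if accepted:
            if config.retrain_from_scratch and initial_weights is not None:
                model.network.set_weights(initial_weights)
            pseudo_idx = np.array([id_to_index[r.sample_id] for r in merged])
            images = np.concatenate([train_set.images, pool.images[pseudo_idx]])
            labels = np.concatenate([train_set.labels, [r.label for r in merged]])
            weights = _lambda_weights(len(train_set), merged, config)
            _fit_single(
                model, images, labels, (val_images, val_labels), config,
                config.epochs_per_ssl_iteration, sample_weights=weights,
            )
        remaining = rejected

    accuracy, report = _evaluate_single(model, test)
    return RunReport(
        mode="ssl_single",
        test_accuracy=accuracy,
        report=report,
        ledger=ledger,
        pseudo_label_precision=_precision_against_hidden(merged, split.hidden_labels),
        n_labelled=len(split.labelled),
        n_merged=len(split.labelled) + len(merged),
        config=config.to_dict(),
        seed=config.seed,
    )


def _run_ssl_consensus_fusion(
    split: SplitResult, test: LabeledDataset, config: RunConfig
) -> RunReport:
    if split.labelled.images.shape[-1] != 1:
        raise ValueError("consensus/fusion mode expects single-channel source images")
    size = split.labelled.images.shape[1]
    eval_tf, _ = _transforms(config)

    # dual views at native size: grayscale as-is, RGB by channel replication
    test_gray_images = test.images
    test_rgb_images = np.repeat(test.images, 3, axis=-1)
    _check_disjoint(split.labelled.sample_ids, test)

    pool_gray = split.unlabelled.images
    pool_rgb = np.repeat(pool_gray, 3, axis=-1)

    train_set, val_images, val_labels = _carve_validation(
        split.labelled, config.validation_fraction, config.seed
    )
    tg = train_set.images
    tr = np.repeat(tg, 3, axis=-1)
    val_g = val_r = None
    if val_images is not None:
        val_g, val_r = val_images, np.repeat(val_images, 3, axis=-1)

    spec_gray = DatasetSpec(tuple(f"c{i}" for i in range(split.labelled.n_classes)), size, size, 1)
    spec_rgb = DatasetSpec(tuple(f"c{i}" for i in range(split.labelled.n_classes)), size, size, 3)
    branch_gray = build_custom_cnn(spec_gray, tiny=config.tiny, seed=config.seed)
    branch_rgb = build_transfer_branch(spec_rgb, seed=config.seed)

    def fit_branch(branch, images, labels, val_imgs, epochs, weights=None):
        branch.fit(
            make_eval_pipeline()(images),
            labels,
            None if val_imgs is None else make_eval_pipeline()(val_imgs),
            val_labels,
            TrainConfig(
                epochs=epochs,
                batch_size=config.train.batch_size,
                learning_rate=config.train.learning_rate,
                lr_callback=config.train.lr_callback,
                seed=config.seed,
                checkpoint_best=config.train.checkpoint_best and val_imgs is not None,
            ),
            sample_weights=weights,
        )

    fit_branch(branch_gray, tg, train_set.labels, val_g, config.train.epochs)
    fit_branch(branch_rgb, tr, train_set.labels, val_r, config.train.epochs)

    id_to_index = {sid: i for i, sid in enumerate(split.unlabelled.sample_ids)}
    remaining = list(split.unlabelled.sample_ids)
    merged: list[PseudoLabelRecord] = []
    ledger = IterationLedger()
    for t, tau in enumerate(config.schedule.thresholds, start=1):
        if not remaining:
            break
        idx = np.array([id_to_index[s] for s in remaining])
        pa = ProbabilityMatrix(
            tuple(remaining), branch_gray.predict_proba(eval_tf(pool_gray[idx]))
        )
        pb = ProbabilityMatrix(
            tuple(remaining), branch_rgb.predict_proba(eval_tf(pool_rgb[idx]))
        )
        accepted, rejected = consensus_vote(
            pa, pb, tau, disagreement_policy=config.disagreement_policy, iteration=t
        )
        ledger.add(t, tau, len(accepted), len(rejected))
        merged.extend(accepted)
        if accepted and config.refresh_branches:
            pseudo_idx = np.array([id_to_index[r.sample_id] for r in merged])
            mg = np.concatenate([tg, pool_gray[pseudo_idx]])
            mr = np.concatenate([tr, pool_rgb[pseudo_idx]])
            ml = np.concatenate([train_set.labels, [r.label for r in merged]])
            weights = _lambda_weights(len(train_set), merged, config)
            fit_branch(branch_gray, mg, ml, val_g, config.epochs_per_ssl_iteration, weights)
            fit_branch(branch_rgb, mr, ml, val_r, config.epochs_per_ssl_iteration, weights)
        remaining = rejected

    # final classifier: fusion head trained on the merged dataset
    pseudo_idx = (
        np.array([id_to_index[r.sample_id] for r in merged], dtype=int)
        if merged
        else np.array([], dtype=int)
    )
    mg = np.concatenate([tg, pool_gray[pseudo_idx]]) if len(pseudo_idx) else tg
    mr = np.concatenate([tr, pool_rgb[pseudo_idx]]) if len(pseudo_idx) else tr
    ml = (
        np.concatenate([train_set.labels, [r.label for r in merged]])
        if merged
        else train_set.labels
    )
    fusion = build_fusion_model(
        branch_gray, branch_rgb, split.labelled.n_classes,
        head_units=64 if config.tiny else 256, seed=config.seed,
    )
    fusion.fit(
        eval_tf(mg),
        eval_tf(mr),
        ml,
        val=None if val_g is None else (eval_tf(val_g), eval_tf(val_r), val_labels),
        config=TrainConfig(
            epochs=config.train.epochs,
            batch_size=config.train.batch_size,
            learning_rate=config.train.learning_rate,
            lr_callback=config.train.lr_callback,
            seed=config.seed,
            checkpoint_best=config.train.checkpoint_best and val_g is not None,
        ),
    )
    preds = fusion.predict_proba(eval_tf(test_gray_images), eval_tf(test_rgb_images)).argmax(axis=1)
    report = classification_report(test.labels, preds, test.n_classes)
    return RunReport(
        mode="ssl_consensus_fusion",
        test_accuracy=report.accuracy,
        report=report,
        ledger=ledger,
        pseudo_label_precision=_precision_against_hidden(merged, split.hidden_labels),
        n_labelled=len(split.labelled),
        n_merged=len(split.labelled) + len(merged),
        config=config.to_dict(),
        seed=config.seed,
    )


def run_ssl(split: SplitResult, test: LabeledDataset, config: RunConfig) -> RunReport:
    """Execute a semi-supervised run (single-model or consensus/fusion)."""
    if len(split.labelled) == 0:
        raise ValueError("labelled set is empty")
    if len(split.unlabelled) == 0:
        raise ValueError("unlabelled pool is empty; use run_supervised_baseline")
    _check_disjoint(split.labelled.sample_ids, test)
    _check_disjoint(split.unlabelled.sample_ids, test)
    if config.mode == "ssl_single":
        return _run_ssl_single(split, test, config)
    if config.mode == "ssl_consensus_fusion":
        return _run_ssl_consensus_fusion(split, test, config)
    raise ValueError(f"run_ssl cannot execute mode {config.mode!r}")


def run_grid(
    data: LabeledDataset,
    test: LabeledDataset,
    fractions: list[float],
    seeds: list[int],
    config: RunConfig,
) -> pd.DataFrame:
    """Cross-product of labelled fractions × seeds; each cell runs the paired
    (supervised baseline, SSL) experiment.  Cell failures are recorded in the
    ``error`` column and the grid continues."""
    if not fractions or not seeds:
        raise ValueError("fractions and seeds must be non-empty")
    rows = []
    for fraction in fractions:
        for seed in seeds:
            cell = {"fraction": fraction, "seed": seed}
            try:
                from dataclasses import replace

                cfg = replace(config, labelled_fraction=fraction, seed=seed)
                split = stratified_split(data, fraction, seed)
                sup = run_supervised_baseline(split, test, cfg)
                cell["supervised_acc"] = sup.test_accuracy
                if len(split.unlabelled) > 0:
                    ssl = run_ssl(split, test, cfg)
                    cell["ssl_acc"] = ssl.test_accuracy
                    cell["pseudo_label_precision"] = ssl.pseudo_label_precision
                    cell["accepted"] = ssl.ledger.total_accepted
                    cell["final_rejected"] = ssl.ledger.final_rejected
                cell["error"] = None
            except Exception as exc:  # pragma: no cover - grid resilience
                cell["error"] = str(exc)
            rows.append(cell)
    return pd.DataFrame(rows)


def phantom_benchmark(
    seeds: "list[int] | None" = None,
    labelled_fraction: float = 0.1,
    per_class_train: int = 50,
    per_class_test: int = 50,
    image_size: int = 32,
    noise_sd: float = 10.0,
    difficulty: float = 0.3,
    config: "RunConfig | None" = None,
) -> pd.DataFrame:
    """Paired supervised-vs-SSL comparison on phantoms at desk scale.

    For each seed, generates a fresh phantom train pool and test set, splits
    the pool at ``labelled_fraction``, and runs the supervised baseline and
    the single-model SSL pipeline with tiny backbones under the full training
    protocol (augmentation, 50-epoch warm-up, full retraining after each
    expansion).  Returns one row per seed with both accuracies (percent) and
    the SSL ledger totals.
    """
    seeds = list(range(10)) if seeds is None else seeds
    rows = []
    for seed in seeds:
        train = generate_phantoms(
            PhantomConfig(per_class_train, image_size, noise_sd, difficulty, seed=seed)
        )
        test = generate_phantoms(
            PhantomConfig(per_class_test, image_size, noise_sd, difficulty, seed=seed + 10_000)
        )
        test = LabeledDataset(
            tuple(f"test/{s}" for s in test.sample_ids), test.images, test.labels, 4
        )
        # desk-scale study conditions: 50-epoch warm-up and full 50-epoch
        # retraining after each expansion, training-time augmentation on,
        # batch 8 sized to the 20-image labelled pool at 10% labels
        base = config or RunConfig(
            mode="ssl_single",
            labelled_fraction=labelled_fraction,
            train=TrainConfig(epochs=50, batch_size=8, seed=seed),
            epochs_per_ssl_iteration=50,
            validation_fraction=0.0,
            augment=AugmentConfig(),
            tiny=True,
            seed=seed,
        )
        from dataclasses import replace

        cfg = replace(base, labelled_fraction=labelled_fraction, seed=seed)
        split = stratified_split(train, labelled_fraction, seed)
        sup = run_supervised_baseline(split, test, cfg)
        ssl = run_ssl(split, test, cfg)
        rows.append(
            {
                "seed": seed,
                "supervised_acc": sup.test_accuracy * 100.0,
                "ssl_acc": ssl.test_accuracy * 100.0,
                "gain": (ssl.test_accuracy - sup.test_accuracy) * 100.0,
                "accepted": ssl.ledger.total_accepted,
                "final_rejected": ssl.ledger.final_rejected,
                "pseudo_label_precision": ssl.pseudo_label_precision,
            }
        )
    return pd.DataFrame(rows)
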