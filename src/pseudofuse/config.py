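"""YAML run configuration: schema-validated loading with defaults, plus an
idempotent dump for provenance manifests."""

from __future__ import annotations

import json
import platform
import sys
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml

from .backbones import LRCallbackConfig, TrainConfig
from .pipeline import RunConfig
from .preprocessing import AugmentConfig
from .pseudolabel import LossConfig, ThresholdSchedule

__all__ = ["load_config", "dump_config", "write_run_manifest"]

_TOP_KEYS = {
    "mode",
    "labelled_fraction",
    "thresholds",
    "lambda",
    "ramp_epochs",
    "epochs",
    "batch_size",
    "learning_rate",
    "epochs_per_ssl_iteration",
    "validation_fraction",
    "tiny",
    "seed",
    "disagreement_policy",
    "augment",
    "lr_callback",
}
_AUG_KEYS = {"horizontal_flip", "rotation_fraction", "contrast_range", "zoom_range", "translate_range"}
_LR_KEYS = {"accuracy_thresholds", "factor", "min_lr"}


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Missing keys take the package defaults (τ schedule [0.98, 0.95, 0.90],
    λ = 1, batch size 32, 50 epochs); unknown keys are rejected by name.  An
    empty file yields the full default configuration.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")

    augment = None
    if raw.get("augment") is not None:
        aug_raw = raw["augment"]
        bad = set(aug_raw) - _AUG_KEYS
        if bad:
            raise ValueError(f"unknown augment key(s): {sorted(bad)}")
        augment = AugmentConfig(**aug_raw)

    lr_callback = LRCallbackConfig()
    if raw.get("lr_callback") is not None:
        lr_raw = dict(raw["lr_callback"])
        bad = set(lr_raw) - _LR_KEYS
        if bad:
            raise ValueError(f"unknown lr_callback key(s): {sorted(bad)}")
        if "accuracy_thresholds" in lr_raw:
            lr_raw["accuracy_thresholds"] = tuple(lr_raw["accuracy_thresholds"])
        lr_callback = LRCallbackConfig(**lr_raw)

    train = TrainConfig(
        epochs=int(raw.get("epochs", 50)),
        batch_size=int(raw.get("batch_size", 32)),
        learning_rate=raw.get("learning_rate"),
        lr_callback=lr_callback,
        seed=int(raw.get("seed", 0)),
    )
    return RunConfig(
        mode=raw.get("mode", "ssl_single"),
        labelled_fraction=float(raw.get("labelled_fraction", 0.1)),
        schedule=ThresholdSchedule(tuple(raw.get("thresholds", (0.98, 0.95, 0.90)))),
        loss=LossConfig(
            lam=float(raw.get("lambda", 1.0)), ramp_epochs=int(raw.get("ramp_epochs", 0))
        ),
        train=train,
        epochs_per_ssl_iteration=int(raw.get("epochs_per_ssl_iteration", 10)),
        validation_fraction=float(raw.get("validation_fraction", 0.1)),
        augment=augment,
        tiny=bool(raw.get("tiny", True)),
        seed=int(raw.get("seed", 0)),
        disagreement_policy=raw.get("disagreement_policy", "reject"),
    )


def dump_config(config: RunConfig) -> str:
    """Serialise a RunConfig back to YAML; ``load(dump(load(x)))`` is stable."""
    doc = {
        "mode": config.mode,
        "labelled_fraction": config.labelled_fraction,
        "thresholds": list(config.schedule.thresholds),
        "lambda": config.loss.lam,
        "ramp_epochs": config.loss.ramp_epochs,
        "epochs": config.train.epochs,
        "batch_size": config.train.batch_size,
        "learning_rate": config.train.learning_rate,
        "epochs_per_ssl_iteration": config.epochs_per_ssl_iteration,
        "validation_fraction": config.validation_fraction,
        "tiny": config.tiny,
        "seed": config.seed,
        "disagreement_policy": config.disagreement_policy,
        "augment": None if config.augment is None else asdict(config.augment),
        "lr_callback": None
        if config.train.lr_callback is None
        else {
            "accuracy_thresholds": list(config.train.lr_callback.accuracy_thresholds),
            "factor": config.train.lr_callback.factor,
            "min_lr": config.train.lr_callback.min_lr,
        },
    }
    return yaml.safe_dump(doc, sort_keys=True)


def write_run_manifest(run_dir: str | Path, command: str, config: RunConfig, seed: int) -> Path:
    """Write the provenance manifest every run directory carries."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config": config.to_dict(),
        "root_seed": seed,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "platform": platform.platform(),
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
    }
    path = run_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
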