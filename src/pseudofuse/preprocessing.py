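"""Training-time augmentation and normalisation.

Training pipeline order is augmentation *then* normalisation (the stochastic
geometric/contrast transforms operate on the raw 8-bit grey scale, then the
result is divided by 255).  Evaluation uses normalisation only and is fully
deterministic.  ``normalize`` refuses input that is already in [0, 1], which
turns silent double-normalisation into a loud failure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["AugmentConfig", "normalize", "augment", "make_eval_pipeline", "make_train_pipeline"]


@dataclass(frozen=True)
class AugmentConfig:
    """Stochastic augmentation ranges.

    ``rotation_fraction`` is a fraction of a full turn (0.02 → ±7.2°);
    ``contrast_range`` a relative scale (0.10 → factor in [0.9, 1.1]);
    ``zoom_range`` and ``translate_range`` relative to the image size.
    """

    horizontal_flip: bool = True
    rotation_fraction: float = 0.02
    contrast_range: float = 0.10
    zoom_range: float = 0.05
    translate_range: float = 0.05

    def __post_init__(self) -> None:
        for name in ("rotation_fraction", "contrast_range", "zoom_range", "translate_range"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def normalize(image: np.ndarray) -> np.ndarray:
    """Map 8-bit grey values to [0, 1] by dividing by 255.

    Raises if any value lies outside [0, 255], or if the image appears to be
    normalised already (all values within [0, 1] while not constant-zero),
    since re-normalising would silently shrink the dynamic range.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.min() < 0 or image.max() > 255:
        raise ValueError("pixel values outside [0, 255]; refusing to normalize")
    if image.size and image.max() <= 1.0 and image.max() > 0:
        raise ValueError("image already appears normalized to [0, 1]")
    return image / 255.0


def _identity_like(config: AugmentConfig) -> bool:
    return (
        not config.horizontal_flip
        and config.rotation_fraction == 0
        and config.contrast_range == 0
        and config.zoom_range == 0
        and config.translate_range == 0
    )


def augment(image: np.ndarray, config: AugmentConfig, draw_seed: int) -> np.ndarray:
    """Apply one random draw of the augmentation pipeline to a single image.

    Flip with probability 0.5; rotation uniform in ±rotation_fraction · 360°;
    contrast scale uniform in 1 ± contrast_range about the image mean; zoom
    uniform in 1 ± zoom_range; translation uniform in ±translate_range · size.
    Bilinear interpolation with reflect padding; output shape equals input
    shape; deterministic per ``draw_seed``.
    """
    image = np.asarray(image, dtype=np.float64)
    squeeze = image.ndim == 2
    if squeeze:
        image = image[:, :, None]
    if _identity_like(config):
        return image[:, :, 0] if squeeze else image

    rng = np.random.default_rng(draw_seed)
    out = image
    if config.horizontal_flip and rng.random() < 0.5:
        out = out[:, ::-1, :]
    angle = rng.uniform(-config.rotation_fraction, config.rotation_fraction) * 360.0
    if angle != 0.0:
        out = ndimage.rotate(out, angle, axes=(1, 0), reshape=False, order=1, mode="reflect")
    if config.zoom_range > 0:
        factor = rng.uniform(1 - config.zoom_range, 1 + config.zoom_range)
        h, w = out.shape[:2]
        zoomed = ndimage.zoom(out, (factor, factor, 1), order=1, mode="reflect")
        zh, zw = zoomed.shape[:2]
        if zh >= h:  # centre crop
            top, left = (zh - h) // 2, (zw - w) // 2
            out = zoomed[top : top + h, left : left + w, :]
        else:  # centre pad by reflection
            pad_h, pad_w = h - zh, w - zw
            out = np.pad(
                zoomed,
                ((pad_h // 2, pad_h - pad_h // 2), (pad_w // 2, pad_w - pad_w // 2), (0, 0)),
                mode="reflect",
            )
    if config.translate_range > 0:
        h, w = out.shape[:2]
        dy = rng.uniform(-config.translate_range, config.translate_range) * h
        dx = rng.uniform(-config.translate_range, config.translate_range) * w
        out = ndimage.shift(out, (dy, dx, 0), order=1, mode="reflect")
    if config.contrast_range > 0:
        scale = rng.uniform(1 - config.contrast_range, 1 + config.contrast_range)
        mean = out.mean()
        out = np.clip(mean + scale * (out - mean), 0.0, 255.0)
    return out[:, :, 0] if squeeze else out


def make_eval_pipeline():
    """Deterministic evaluation transform: normalisation only."""

    def pipeline(batch: np.ndarray) -> np.ndarray:
        return normalize(batch)

    return pipeline


def make_train_pipeline(config: AugmentConfig, seed: int):
    """Training transform: per-image augmentation followed by normalisation.

    Each call consumes fresh draw seeds from a deterministic stream, so two
    pipelines built with the same ``seed`` produce identical augmented batches
    call-for-call.
    """
    seq = np.random.SeedSequence(seed)

    def pipeline(batch: np.ndarray) -> np.ndarray:
        batch = np.asarray(batch, dtype=np.float64)
        draws = seq.spawn(len(batch))
        out = np.stack(
            [
                augment(img, config, int(d.generate_state(1)[0] % (2**31)))
                for img, d in zip(batch, draws)
            ]
        )
        return normalize(out)

    return pipeline
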