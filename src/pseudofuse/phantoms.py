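"""Seeded generator of four-class grayscale phantom images.

The phantoms stand in, at desk scale, for a four-class tumor-MRI task: each
image is a smooth elliptical "brain" background plus, for three of the four
classes, a distinct bright lesion:

* class 0 — eccentric bright ellipse with a ragged (angularly perturbed) edge,
* class 1 — bright ring (annulus),
* class 2 — small high-intensity disc confined to the lower half,
* class 3 — background ellipse only, no lesion.

Classes 0 and 1 are deliberately the most confusable pair (a ragged filled
ellipse vs. a thick ring).  A ``difficulty`` knob in [0, 1] pulls lesion
contrast toward the background, and ``noise_sd`` adds Gaussian pixel noise on
the 8-bit grey scale.  Pose jitter (±10% translation, rotation of the lesion
axes) is part of generation itself and is distinct from training-time
augmentation.  Generation is byte-deterministic for a fixed config.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

from .data import DatasetSpec, LabeledDataset

__all__ = ["PhantomConfig", "generate_phantoms", "render_dual_views", "phantom_spec", "CLASS_NAMES"]

CLASS_NAMES = ("ragged_mass", "ring", "focal_disc", "clear")

BACKGROUND = 80.0  # grey level of the brain ellipse
LESION_PEAK = 230.0  # lesion grey level at difficulty 0


@dataclass(frozen=True)
class PhantomConfig:
    """Generation parameters.

    ``noise_sd`` is in grey-level units on the [0, 255] scale; ``difficulty``
    in [0, 1] linearly interpolates lesion contrast toward the background
    (0 = full contrast, 1 = lesions nearly invisible).
    """

    per_class_count: int = 50
    image_size: int = 64
    noise_sd: float = 10.0
    difficulty: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.per_class_count < 1:
            raise ValueError("per_class_count must be >= 1")
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if not (0.0 <= self.difficulty <= 1.0):
            raise ValueError("difficulty must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def phantom_spec(config: PhantomConfig) -> DatasetSpec:
    return DatasetSpec(CLASS_NAMES, config.image_size, config.image_size, channels=1)


def _grid(size: int) -> tuple[np.ndarray, np.ndarray]:
    # coordinates in [-1, 1]
    ax = np.linspace(-1.0, 1.0, size)
    return np.meshgrid(ax, ax, indexing="xy")


def _rotate(x: np.ndarray, y: np.ndarray, angle: float) -> tuple[np.ndarray, np.ndarray]:
    c, s = np.cos(angle), np.sin(angle)
    return c * x + s * y, -s * x + c * y


def _brain_background(size: int, level: float) -> np.ndarray:
    """Smooth elliptical background with a soft radial falloff."""
    x, y = _grid(size)
    r2 = (x / 0.88) ** 2 + (y / 0.95) ** 2
    inside = r2 <= 1.0
    img = np.zeros((size, size))
    img[inside] = level * (1.0 - 0.25 * r2[inside])
    return img


def _lesion_mask(cls: int, size: int, rng: np.random.Generator, difficulty: float) -> np.ndarray:
    """Boolean lesion mask for one sample of class ``cls`` with pose jitter.

    Jitter: translation up to ±18% of the field, rotation of the lesion
    frame up to ±18°, isotropic size scale in [0.75, 1.25].  ``difficulty``
    also shrinks the ring's central hole, pulling class 1 toward class 0's
    filled-mass geometry (their confusability is the intended hardest pair).
    """
    x, y = _grid(size)
    dx, dy = rng.uniform(-0.18, 0.18, size=2)
    theta = rng.uniform(-np.pi / 10, np.pi / 10)
    xr, yr = _rotate(x - dx, y - dy, theta)
    scale = rng.uniform(0.75, 1.25)

    if cls == 0:  # eccentric ragged ellipse
        a, b = 0.38 * scale, 0.27 * scale
        phi = np.arctan2(yr, xr)
        # ragged edge: low-order angular harmonics with random phases
        ragged = 1.0 + 0.20 * np.sin(5 * phi + rng.uniform(0, 2 * np.pi)) + 0.14 * np.sin(
            9 * phi + rng.uniform(0, 2 * np.pi)
        )
        r2 = (xr / a) ** 2 + (yr / b) ** 2
        return r2 <= ragged
    if cls == 1:  # bright ring; hole shrinks with difficulty
        r = np.sqrt((xr / (0.40 * scale)) ** 2 + (yr / (0.33 * scale)) ** 2)
        inner = max(0.60 - 0.5 * difficulty, 0.1)
        return (r >= inner) & (r <= 1.0)
    if cls == 2:  # small bright disc, lower half
        cx = rng.uniform(-0.3, 0.3)
        cy = rng.uniform(0.25, 0.55)  # image y grows downward in array order
        rr = 0.15 * scale
        r2 = ((x - cx) / rr) ** 2 + ((y - cy) / rr) ** 2
        return r2 <= 1.0
    return np.zeros((size, size), dtype=bool)  # class 3: no lesion


def generate_phantoms(config: PhantomConfig) -> LabeledDataset:
    """Generate ``4 * per_class_count`` phantom images, exactly balanced.

    Each sample draws its own background level (~N(80, 12²) grey) and lesion
    intensity — a fraction of the difficulty-scaled contrast — so that no
    single global grey-level statistic separates the classes.  Pixel values
    are clipped to [0, 255] and stored as floats (8-bit grid on disk, via
    :func:`pseudofuse.data.write_image_folder`).
    """
    rng = np.random.default_rng(config.seed)
    size = config.image_size
    contrast = (LESION_PEAK - BACKGROUND) * (1.0 - config.difficulty) ** 2

    ids: list[str] = []
    images: list[np.ndarray] = []
    labels: list[int] = []
    for cls in range(4):
        for k in range(config.per_class_count):
            bg = rng.normal(BACKGROUND, 12.0)
            background = _brain_background(size, bg)
            brain = background > 0
            lesion_level = bg + contrast * rng.uniform(0.55, 1.0)
            img = background.copy()
            mask = _lesion_mask(cls, size, rng, config.difficulty) & brain
            img[mask] = lesion_level
            if config.noise_sd > 0:
                img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
            img = np.clip(img, 0.0, 255.0)
            ids.append(f"{CLASS_NAMES[cls]}/{CLASS_NAMES[cls]}_{k:04d}.png")
            images.append(img[:, :, None])
            labels.append(cls)
    return LabeledDataset(tuple(ids), np.stack(images), np.array(labels), 4)


def _resize_stack(images: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resize of an (n, H, W, 1) stack to (n, size, size, 1)."""
    out = np.empty((len(images), size, size, 1))
    for i, img in enumerate(images):
        pil = Image.fromarray(np.clip(img[:, :, 0], 0, 255).astype(np.float32), mode="F")
        out[i, :, :, 0] = np.asarray(pil.resize((size, size), Image.BILINEAR))
    return out


def render_dual_views(
    data: LabeledDataset, gray_size: int = 168, rgb_size: int = 224
) -> tuple[LabeledDataset, LabeledDataset]:
    """Render the grayscale and channel-replicated RGB views of one dataset.

    The grayscale view is resized to ``gray_size``² × 1 and the RGB view to
    ``rgb_size``² × 3 by replicating the single channel three times (the
    channels are therefore identical).  Sample ids and ordering match between
    views.
    """
    if data.images.shape[-1] != 1:
        raise ValueError("render_dual_views expects single-channel input")
    gray = _resize_stack(data.images, gray_size)
    rgb1 = _resize_stack(data.images, rgb_size)
    rgb = np.repeat(rgb1, 3, axis=-1)
    return (
        LabeledDataset(data.sample_ids, gray, data.labels, data.n_classes),
        LabeledDataset(data.sample_ids, rgb, data.labels, data.n_classes),
    )
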