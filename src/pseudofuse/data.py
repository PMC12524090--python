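"""Dataset containers, stratified labelled/unlabelled splitting, and image-folder I/O.

Images live in memory as ``float64`` arrays of shape ``(H, W, channels)`` with raw
8-bit grey values in ``[0, 255]``; normalisation to ``[0, 1]`` is a separate,
explicit preprocessing step so that double-normalisation bugs are detectable.
Class indices are 0-based everywhere inside the library; class *names* appear
only at I/O boundaries (directory names, manifests).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "DatasetSpec",
    "LabeledDataset",
    "UnlabeledPool",
    "SplitResult",
    "stratified_split",
    "read_image_folder",
    "write_image_folder",
    "write_split_manifest",
]


@dataclass(frozen=True)
class DatasetSpec:
    """Shape contract for a classification dataset.

    Parameters
    ----------
    class_names:
        Ordered class names; the position of a name is its integer class index.
    image_height, image_width:
        Pixel dimensions every image must share.
    channels:
        1 (grayscale) or 3 (RGB).
    """

    class_names: tuple[str, ...]
    image_height: int
    image_width: int
    channels: int = 1

    def __post_init__(self) -> None:
        if len(self.class_names) < 2:
            raise ValueError("need at least 2 classes")
        if len(set(self.class_names)) != len(self.class_names):
            raise ValueError("class names must be unique")
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image dimensions must be positive")
        if self.channels not in (1, 3):
            raise ValueError("channels must be 1 or 3")
        object.__setattr__(self, "class_names", tuple(self.class_names))

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.image_height, self.image_width, self.channels)


def _check_images(images: np.ndarray) -> np.ndarray:
    images = np.asarray(images, dtype=np.float64)
    if images.ndim != 4:
        raise ValueError(f"expected (n, H, W, C) image stack, got shape {images.shape}")
    return images


def _check_unique(ids: tuple[str, ...]) -> None:
    if len(set(ids)) != len(ids):
        raise ValueError("sample_ids must be unique")


@dataclass(frozen=True)
class LabeledDataset:
    """Images with integer class labels (the labelled pool D_l)."""

    sample_ids: tuple[str, ...]
    images: np.ndarray  # (n, H, W, C)
    labels: np.ndarray  # (n,) ints
    n_classes: int

    def __post_init__(self) -> None:
        images = _check_images(self.images)
        labels = np.asarray(self.labels, dtype=np.int64)
        ids = tuple(str(s) for s in self.sample_ids)
        if not (len(ids) == len(images) == len(labels)):
            raise ValueError("sample_ids, images and labels must align")
        _check_unique(ids)
        if len(labels) and (labels.min() < 0 or labels.max() >= self.n_classes):
            raise ValueError("labels out of range")
        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "images", images)
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.sample_ids)

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        idx = np.asarray(idx)
        return LabeledDataset(
            tuple(self.sample_ids[i] for i in idx),
            self.images[idx],
            self.labels[idx],
            self.n_classes,
        )

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)


@dataclass(frozen=True)
class UnlabeledPool:
    """Images without labels (the unlabelled pool D_u)."""

    sample_ids: tuple[str, ...]
    images: np.ndarray

    def __post_init__(self) -> None:
        images = _check_images(self.images)
        ids = tuple(str(s) for s in self.sample_ids)
        if len(ids) != len(images):
            raise ValueError("sample_ids and images must align")
        _check_unique(ids)
        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "images", images)

    def __len__(self) -> int:
        return len(self.sample_ids)

    def subset(self, idx: np.ndarray) -> "UnlabeledPool":
        idx = np.asarray(idx)
        return UnlabeledPool(tuple(self.sample_ids[i] for i in idx), self.images[idx])


@dataclass(frozen=True)
class SplitResult:
    """Outcome of a stratified labelled/unlabelled partition.

    ``hidden_labels`` keeps the ground truth of the unlabelled pool so that
    pseudo-label precision can be measured on synthetic data.  Training code
    accepts only ``UnlabeledPool``, which carries no labels, so the hidden
    truth cannot leak into fitting.
    """

    labelled: LabeledDataset
    unlabelled: UnlabeledPool
    hidden_labels: dict[str, int]
    seed: int


def stratified_split(data: LabeledDataset, labelled_fraction: float, seed: int) -> SplitResult:
    """Partition ``data`` into labelled/unlabelled pools, stratified by class.

    Per-class labelled counts follow the largest-remainder rule: the total
    labelled count is ``round(fraction * n)``; each class starts from
    ``floor(fraction * n_c)`` and the leftover slots go to the classes with
    the largest fractional parts (ties broken by class index).  Deterministic
    for a fixed ``(data, fraction, seed)``.
    """
    if not (0.0 < labelled_fraction <= 1.0):
        raise ValueError("labelled_fraction must be in (0, 1]")
    counts = data.class_counts()
    for c, n_c in enumerate(counts):
        if n_c == 0:
            raise ValueError(f"class {c} has no samples; cannot stratify")

    n = len(data)
    total_target = int(round(labelled_fraction * n))
    ideal = labelled_fraction * counts
    base = np.floor(ideal).astype(int)
    remainder = total_target - int(base.sum())
    if remainder > 0:
        frac = ideal - base
        order = np.lexsort((np.arange(len(counts)), -frac))
        for c in order[:remainder]:
            base[c] += 1
    base = np.minimum(base, counts)  # guard degenerate roundings

    rng = np.random.default_rng(seed)
    lab_idx: list[int] = []
    unlab_idx: list[int] = []
    for c, take in enumerate(base):
        members = np.flatnonzero(data.labels == c)
        perm = rng.permutation(len(members))
        lab_idx.extend(members[perm[:take]])
        unlab_idx.extend(members[perm[take:]])
    lab_idx_arr = np.sort(np.array(lab_idx, dtype=int))
    unlab_idx_arr = np.sort(np.array(unlab_idx, dtype=int))

    labelled = data.subset(lab_idx_arr)
    unlabelled = UnlabeledPool(
        tuple(data.sample_ids[i] for i in unlab_idx_arr), data.images[unlab_idx_arr]
    )
    hidden = {data.sample_ids[i]: int(data.labels[i]) for i in unlab_idx_arr}
    return SplitResult(labelled=labelled, unlabelled=unlabelled, hidden_labels=hidden, seed=seed)


def read_image_folder(root_path: str | Path, spec: DatasetSpec) -> LabeledDataset:
    """Read a ``root/<class_name>/<file>.png`` tree into a :class:`LabeledDataset`.

    Ordering is deterministic (lexicographic by path).  Subdirectories that are
    not in ``spec.class_names`` are an error, as is an empty class directory.
    """
    root = Path(root_path)
    if not root.is_dir():
        raise FileNotFoundError(f"no such directory: {root}")
    known = set(spec.class_names)
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        if sub.name not in known:
            raise ValueError(f"unknown class directory: {sub.name!r}")

    ids: list[str] = []
    images: list[np.ndarray] = []
    labels: list[int] = []
    for label, name in enumerate(spec.class_names):
        class_dir = root / name
        if not class_dir.is_dir():
            raise FileNotFoundError(f"missing class directory: {class_dir}")
        files = sorted(p for p in class_dir.iterdir() if p.is_file())
        if not files:
            raise ValueError(f"class directory {class_dir} is empty")
        for path in files:
            try:
                with Image.open(path) as im:
                    im = im.convert("L" if spec.channels == 1 else "RGB")
                    arr = np.asarray(im, dtype=np.float64)
            except Exception as exc:  # decoding failure names the file
                raise ValueError(f"cannot decode image file {path}: {exc}") from exc
            if arr.ndim == 2:
                arr = arr[:, :, None]
            if arr.shape != spec.shape:
                raise ValueError(
                    f"{path}: image shape {arr.shape} does not match spec {spec.shape}"
                )
            ids.append(f"{name}/{path.name}")
            images.append(arr)
            labels.append(label)
    return LabeledDataset(tuple(ids), np.stack(images), np.array(labels), spec.n_classes)


def write_image_folder(
    data: LabeledDataset,
    root_path: str | Path,
    class_names: "tuple[str, ...] | list[str] | None" = None,
    overwrite: bool = False,
) -> list[dict]:
    """Write one 8-bit PNG per sample under its class directory.

    Returns a manifest of ``{"sample_id", "path", "label"}`` rows.  Raises on
    collision with an existing file unless ``overwrite`` is set.  An empty
    dataset writes nothing and creates no directories.
    """
    root = Path(root_path)
    if class_names is None:
        class_names = [f"class_{c}" for c in range(data.n_classes)]
    if len(class_names) != data.n_classes:
        raise ValueError("class_names length must equal n_classes")

    manifest: list[dict] = []
    for sid, img, label in zip(data.sample_ids, data.images, data.labels):
        class_dir = root / class_names[int(label)]
        class_dir.mkdir(parents=True, exist_ok=True)
        stem = sid.split("/")[-1]
        if not stem.endswith(".png"):
            stem += ".png"
        path = class_dir / stem
        if path.exists() and not overwrite:
            raise FileExistsError(f"refusing to overwrite {path}")
        arr = np.clip(np.round(img), 0, 255).astype(np.uint8)
        if arr.shape[-1] == 1:
            Image.fromarray(arr[:, :, 0], mode="L").save(path)
        else:
            Image.fromarray(arr, mode="RGB").save(path)
        manifest.append({"sample_id": sid, "path": str(path), "label": int(label)})
    return manifest


def write_split_manifest(split: SplitResult, path: str | Path, test: LabeledDataset | None = None) -> None:
    """Write a CSV manifest (sample_id, role, label_or_NA, seed) for a split."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "role", "label_or_NA", "seed"])
        for sid, label in zip(split.labelled.sample_ids, split.labelled.labels):
            writer.writerow([sid, "labelled", int(label), split.seed])
        for sid in split.unlabelled.sample_ids:
            writer.writerow([sid, "unlabelled", "NA", split.seed])
        if test is not None:
            for sid, label in zip(test.sample_ids, test.labels):
                writer.writerow([sid, "test", int(label), split.seed])
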