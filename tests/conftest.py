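import numpy as np
import pytest

from pseudofuse.data import DatasetSpec, LabeledDataset
from pseudofuse.phantoms import PhantomConfig, generate_phantoms


@pytest.fixture(scope="session")
def tiny_spec() -> DatasetSpec:
    return DatasetSpec(("a", "b", "c", "d"), 32, 32, 1)


@pytest.fixture(scope="session")
def phantoms_small() -> LabeledDataset:
    """40 phantoms (10/class) at 32 px, shared across tests."""
    return generate_phantoms(PhantomConfig(per_class_count=10, image_size=32, seed=0))


@pytest.fixture(scope="session")
def phantoms_default64() -> LabeledDataset:
    """The generator's default configuration (50/class at 64 px, seed 0)."""
    return generate_phantoms(PhantomConfig())


def make_two_blob_toy(n: int = 40, size: int = 32, seed: int = 0) -> LabeledDataset:
    """Linearly separable two-class image toy: bright left vs right half."""
    rng = np.random.default_rng(seed)
    images, labels = [], []
    for i in range(n):
        img = np.zeros((size, size, 1))
        cls = i % 2
        if cls == 0:
            img[:, : size // 2, 0] = 200.0
        else:
            img[:, size // 2 :, 0] = 200.0
        img = np.clip(img + rng.normal(0, 5, img.shape), 0, 255)
        images.append(img)
        labels.append(cls)
    return LabeledDataset(
        tuple(f"s{i}" for i in range(n)), np.stack(images), np.array(labels), 2
    )
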