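import numpy as np
import pytest

from hybridseg.model import ArchitectureConfig, HybridUNet
from hybridseg.phantoms import PhantomConfig, generate_dataset, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_config():
    """Smallest architecture that still exercises every code path."""
    return ArchitectureConfig(
        base_channels=4, input_size=32, transformer_layers=1, attention_heads=4
    )


@pytest.fixture
def tiny_model(tiny_config):
    return HybridUNet(tiny_config, np.random.default_rng(7))


@pytest.fixture(scope="session")
def default_model():
    """Full-scale model at the default configuration (shared: slow to run)."""
    return HybridUNet(ArchitectureConfig(), np.random.default_rng(0))


@pytest.fixture
def phantom_batch():
    """Eight 32px ultrasound phantoms as a (8,3,32,32) batch plus masks."""
    cfg = PhantomConfig(modality="ultrasound", image_size=32, seed=3)
    gen = np.random.default_rng(3)
    imgs, masks = [], []
    for _ in range(8):
        img, mask, _ = generate_phantom(cfg, gen)
        imgs.append(np.repeat(img[None], 3, axis=0).astype(np.float32))
        masks.append(mask)
    return np.stack(imgs), np.stack(masks)


@pytest.fixture
def phantom_dataset(tmp_path):
    """Written-to-disk synthetic dataset: 6 patients x 2 images at 32px."""
    cfg = PhantomConfig(
        modality="mammogram", image_size=32, patients=6, images_per_patient=2, seed=1
    )
    manifest = generate_dataset(cfg, tmp_path / "data")
    return tmp_path / "data" / "manifest.csv", manifest
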