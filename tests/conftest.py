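import numpy as np
import pytest

from cardseg.dataio import GrayImage, LabelMap
from cardseg.phantoms import PhantomConfig, generate_dataset, generate_phantom


#: small-grid phantom geometry used by fast tests (structures scaled to fit)
SMALL_CONFIG = PhantomConfig(
    rows=64, cols=64, lv_radius=10, myo_thickness=4, rv_offset=7, rv_thickness=5
)


@pytest.fixture(scope="session")
def small_phantom_config() -> PhantomConfig:
    return SMALL_CONFIG


@pytest.fixture(scope="session")
def phantom_pair():
    """One deterministic mid-slice phantom image/label pair (64x64)."""
    return generate_phantom(SMALL_CONFIG, seed=42)


@pytest.fixture(scope="session")
def unit_phantom_pair(phantom_pair):
    """The same pair with the image scaled to unit floats (no CLAHE)."""
    image, label = phantom_pair
    unit = GrayImage(image.pixels.astype(np.float64) / 65535.0, "float")
    return unit, label


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A 24-frame mixed phantom dataset on disk with a manifest."""
    out = tmp_path_factory.mktemp("phantom_data")
    manifest = generate_dataset(24, SMALL_CONFIG, seed=7, out_dir=out, splits=(2 / 3, 1 / 6, 1 / 6))
    return manifest, out


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def float64_engine(monkeypatch):
    """Run the NumPy CNN engine in float64 for finite-difference checks."""
    import cardseg.model as model_mod
    import cardseg.nn as nn_mod

    monkeypatch.setattr(nn_mod, "F32", np.float64)
    monkeypatch.setattr(model_mod, "F32", np.float64)


def random_prob_stack(rng: np.random.Generator, k: int, m: int) -> np.ndarray:
    """Random (K, M) probabilities summing to 1 per pixel column."""
    y = rng.random((k, m))
    return y / y.sum(axis=0, keepdims=True)


def random_onehot_stack(rng: np.random.Generator, k: int, m: int, present_all: bool = False) -> np.ndarray:
    labels = rng.integers(0, k, size=m)
    if present_all:
        labels[:k] = np.arange(k)  # force every class to appear
    t = np.zeros((k, m))
    t[labels, np.arange(m)] = 1.0
    return t
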