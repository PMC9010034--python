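import numpy as np
import pytest

from spfn import (
    Image2D,
    ImagePair,
    ModelConfig,
    PhantomConfig,
    generate_phantom_pair,
    init_parameters,
    make_pair,
    minmax_normalize,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240131)


@pytest.fixture(scope="session")
def phantom_pair_64():
    """One 64x64 registered phantom, normalized and fusion-ready."""
    ph = generate_phantom_pair(PhantomConfig(ct_size=64, seed=7))
    return make_pair(ph.ct, ph.pet_native, identifier="ph64")


@pytest.fixture(scope="session")
def identity_pair_32():
    """ct = pet fixture: the same full-range 32x32 anatomy as both modalities."""
    ph = generate_phantom_pair(PhantomConfig(ct_size=32, pet_native_size=8, seed=5))
    ct = minmax_normalize(ph.ct)
    pet = Image2D(ct.values, modality="PET", normalized=True)
    return ImagePair(ct=ct, pet=pet, identifier="identity32")


@pytest.fixture(scope="session")
def small_model():
    """Default-architecture parameters at a fixed seed (session-cached)."""
    cfg = ModelConfig()
    return cfg, init_parameters(cfg, seed=0)
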