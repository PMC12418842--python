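import numpy as np
import pytest

from macpheno.gp import ChannelPair
from macpheno.synthetic import (SyntheticImageSpec, generate_membrane_images)


@pytest.fixture(scope="session")
def noiseless_field():
    """One noise-free field of ring cells at gp_true = 0.5."""
    spec = SyntheticImageSpec(image_size=(120, 120), n_cells=6, gp_true=0.5,
                              photon_budget=2000.0, background_rate=20.0,
                              seed=3, noise=False)
    return generate_membrane_images(spec, phenotype="M1")


@pytest.fixture(scope="session")
def noisy_field():
    """Poisson-noise field at gp_true = 0.3, photon budget 2000."""
    spec = SyntheticImageSpec(image_size=(160, 160), n_cells=10, gp_true=0.3,
                              photon_budget=2000.0, background_rate=20.0,
                              seed=7, noise=True)
    return generate_membrane_images(spec, phenotype="M0")


@pytest.fixture
def uniform_pair():
    """Flat 8x8 channel pair with raw GP 0.5 (ordered 3, disordered 1)."""
    return ChannelPair(np.full((8, 8), 3.0), np.full((8, 8), 1.0))
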