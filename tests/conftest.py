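import numpy as np
import pytest

from morphomod.io import Dataset, LandmarkConfiguration
from morphomod.simulate import GroupSpec, SimulationConfig, generate_dataset
from morphomod.superimposition import PairingScheme


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


# a small bilaterally symmetric scheme: 3 pairs + 2 midline = 8 landmarks
@pytest.fixture
def small_pairing():
    return PairingScheme(paired=((0, 1), (2, 3), (4, 5)), midline=(6, 7))


@pytest.fixture
def small_symmetric_config(small_pairing):
    """Simulation config for a small symmetric 3D dataset, two groups."""
    return SimulationConfig(
        k=8,
        m=3,
        pairing=small_pairing,
        groups=[GroupSpec("a", 12, 0.0), GroupSpec("b", 12, 10.0)],
        module_map=None,
        rho_within=0.4,
        rho_between=0.1,
        noise_sd=1.0,
        asymmetry_sd=0.2,
        seed=7,
    )


@pytest.fixture
def small_dataset(small_symmetric_config):
    return generate_dataset(small_symmetric_config)


def make_dataset(coords, ids=None, groups=None):
    coords = np.asarray(coords, float)
    if ids is None:
        ids = [f"s{i}" for i in range(coords.shape[0])]
    configs = [LandmarkConfiguration(i, c) for i, c in zip(ids, coords)]
    labels = None if groups is None else np.asarray(groups)
    return Dataset(configs, metadata=None, group_labels=labels)
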