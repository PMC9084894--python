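import numpy as np
import pytest

from synaptrack import Geometry, OpticsConfig, SimulationConfig, simulate_ground_truth


@pytest.fixture(scope="session")
def simple_geometry() -> Geometry:
    """A 10 x 3 µm dendrite with three synapses."""
    return Geometry(
        dendrite_rect=(0.0, 0.0, 10.0, 3.0),
        synapses=((2.0, 1.5, 0.3), (5.0, 1.0, 0.3), (8.0, 2.0, 0.3)),
    )


@pytest.fixture(scope="session")
def default_optics() -> OpticsConfig:
    return OpticsConfig()


@pytest.fixture(scope="session")
def free_truth(simple_geometry):
    """Purely mobile molecules (no immobile pool), moderate size."""
    cfg = SimulationConfig(D_free=0.30, immobile_fraction=0.0,
                           n_molecules=200, n_frames=1000, seed=7)
    return simulate_ground_truth(cfg, simple_geometry)


@pytest.fixture(scope="session")
def div8_truth(simple_geometry):
    """Two-state mixture: 20% immobile anchored at synapses."""
    cfg = SimulationConfig(D_free=0.30, immobile_fraction=0.20,
                           n_molecules=300, n_frames=1500, seed=11)
    return simulate_ground_truth(cfg, simple_geometry)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
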