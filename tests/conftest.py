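import numpy as np
import pytest

from climshift import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """A reduced study frame that keeps every pipeline stage fast."""
    return SimulationConfig(
        n_provinces=12,
        n_species=40,
        lat_range=(55.0, 65.0),
        lon_range=(12.0, 24.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return simulate_dataset(small_cfg, cell_area_km2=6000.0)


@pytest.fixture(scope="session")
def default_dataset():
    """The full emulated study frame: 51 provinces, 131 species, 5 censuses."""
    return simulate_dataset(SimulationConfig(seed=1))
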