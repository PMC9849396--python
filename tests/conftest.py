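import numpy as np
import pytest

from parep.grid import GridSpec
from parep.synthetic import (
    DecadeSpec,
    GroupConfig,
    SyntheticWorldConfig,
    generate_world,
)


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    return GridSpec(12, 12, cell_side=2.0)


def small_world_config(seed: int = 11) -> SyntheticWorldConfig:
    """A compact world: 30×30 cells (~4500 km²), 46 species, 4 decades."""
    return SyntheticWorldConfig(
        seed=seed,
        grid=GridSpec(30, 30),
        groups={
            "bird": GroupConfig(12, median_range_km2=1200.0, log_sd=0.7,
                                elev_pref=400.0, elev_sd=700.0),
            "mammal": GroupConfig(6, median_range_km2=1000.0, log_sd=0.7,
                                  elev_pref=400.0, elev_sd=700.0),
            "amphibian": GroupConfig(8, median_range_km2=120.0, log_sd=0.9,
                                     elev_pref=2200.0, elev_sd=500.0,
                                     dispersal_km=5.0),
            "reptile": GroupConfig(6, median_range_km2=160.0, log_sd=0.9,
                                   elev_pref=2000.0, elev_sd=500.0,
                                   dispersal_km=5.0),
            "plant": GroupConfig(14, median_range_km2=400.0, log_sd=1.0,
                                 elev_pref=1200.0, elev_sd=900.0,
                                 dispersal_km=5.0),
        },
        pa_history=[
            DecadeSpec("1976-1985", 1976, 1985, 2, 220.0, 2400.0),
            DecadeSpec("1986-1995", 1986, 1995, 3, 420.0, 1800.0),
            DecadeSpec("1996-2005", 1996, 2005, 3, 320.0, 1200.0),
            DecadeSpec("2006-2015", 2006, 2015, 2, 240.0, 800.0),
        ],
    )


@pytest.fixture(scope="session")
def small_world():
    return generate_world(small_world_config())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
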