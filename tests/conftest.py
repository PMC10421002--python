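import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from forestcarbon import (ECOZONES, ForestType, ForestTypeRegistry,
                          SpeciesParams, SpeciesTable, StandParams,
                          SyntheticConfig, VolumeEquationSpec,
                          generate_dataset, load_registry)

settings.register_profile("suite", max_examples=50, derandomize=True,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_registry():
    return load_registry()


def make_toy_world(*, b=0.002, ef=1.0, d=0.5, cf=0.5, n_stems=500.0,
                   dbh=30.0, dbh_sd=3.0, h=20.0, h_sd=0.0, area_ha=1000.0,
                   growth=0.05, mortality=0.01):
    """One-type world with stem volume LINEAR in DBH (V = b*DBH, m^3).

    Carbon is then an affine function of the DBH draw, which gives the Monte
    Carlo tests a closed-form normal reference distribution.
    """
    eq = VolumeEquationSpec(form="linear", coefficients=(0.0, b, 0.0))
    species = SpeciesTable([
        SpeciesParams(species="toy_sp", ef=ef, d=d, cf=cf,
                      volume_equations={z: eq for z in ECOZONES})])
    ftype = ForestType(abbreviation="TOY-NF", name="Toy Forest",
                       wood_type="coniferous", regeneration="nature",
                       species_weights=(("toy_sp", 1.0),))
    registry = ForestTypeRegistry([ftype], species_groups={})
    stands = {"TOY-NF": StandParams(
        abbreviation="TOY-NF", dbh_mean=dbh, dbh_sd=dbh_sd, h_mean=h,
        h_sd=h_sd, n_stems_ha=n_stems, growth_rate=growth,
        mortality_rate=mortality)}
    areas = pd.DataFrame({"forest_type": ["TOY-NF"], "ecozone": [ECOZONES[0]],
                          "area_ha": [area_ha]})
    # carbon = slope * DBH for the linear toy
    slope = area_ha * n_stems * b * ef * d * cf
    return registry, species, stands, areas, slope


@pytest.fixture()
def toy_world():
    return make_toy_world()


@pytest.fixture(scope="session")
def synthetic_dataset():
    """A 12x12 synthetic dataset shared by the slower integration tests."""
    config = SyntheticConfig(seed=123, nrows=12, ncols=12)
    registry, species, stands, landscape, tables = generate_dataset(config)
    return {"config": config, "registry": registry, "species": species,
            "stands": stands, "landscape": landscape, "tables": tables}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
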