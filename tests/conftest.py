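import math

import numpy as np
import pytest

from thermoniche import (
    ConsumptionParams,
    DietItem,
    DietSchedule,
    EnergyDensityModel,
    RespirationParams,
    SpeciesParams,
    WasteParams,
    default_models,
    load_species,
)
from thermoniche.energy_density import EDSegment
from thermoniche.io import packaged_diet
from thermoniche.scenarios import TemperatureScenario


@pytest.fixture(scope="session")
def lt_params() -> SpeciesParams:
    return load_species("lake_trout")


@pytest.fixture(scope="session")
def cs_params() -> SpeciesParams:
    return load_species("chinook_salmon")


@pytest.fixture(scope="session")
def lt_diet() -> DietSchedule:
    return packaged_diet("lake_trout")


@pytest.fixture(scope="session")
def cs_diet() -> DietSchedule:
    return packaged_diet("chinook_salmon")


@pytest.fixture(scope="session")
def simple_diet() -> DietSchedule:
    """Single prey, 5000 J/g, fully digestible."""
    return DietSchedule(items=(DietItem("prey", 1.0, 5000.0, 0.0),))


@pytest.fixture(scope="session")
def ed_models() -> dict[str, EnergyDensityModel]:
    return default_models()


@pytest.fixture(scope="session")
def flat_ed() -> EnergyDensityModel:
    """Constant 6 kJ/g energy density (slope zero): weight = energy / 6000."""
    return EnergyDensityModel(segments=(EDSegment(6.0, 0.0, 0.0, math.inf),))


@pytest.fixture(scope="session")
def lt_observed_scenario(lt_params) -> TemperatureScenario:
    """A fixed, deterministic lake-trout-like observed annual cycle."""
    nodes = [2.8, 3.8, 4.9, 6.1, 6.9, 7.1, 9.3, 9.5, 5.4, 3.5, 2.5, 2.3, 2.7]
    return TemperatureScenario.from_nodes("observed", lt_params.sim_start, nodes)


def make_toy_params(
    *,
    CA: float = 0.05,
    CB: float = 0.0,
    RA: float = 0.002,
    RB: float = 0.0,
    SDA: float = 0.1,
    FA: float = 0.2,
    UA: float = 0.05,
) -> SpeciesParams:
    """Weight-independent consumption/respiration with proportional waste:
    under constant temperature and a flat ED model the daily recursion is
    exactly geometric, giving a closed-form oracle."""
    p = SpeciesParams(
        name="toy",
        consumption=ConsumptionParams(CA=CA, CB=CB, CEQ=2, CQ=2.3, CTO=10.0, CTM=25.0),
        respiration=RespirationParams(
            RA=RA, RB=RB, REQ=2, RQ=2.1, RTO=10.0, RTM=25.0, ACT=1.5, SDA=SDA
        ),
        waste=WasteParams(FEQ=1, UEQ=1, FA=FA, UA=UA),
        optimum_temp=10.0,
        sim_start=(4, 1),
        start_weight=100.0,
        age_span=(1, 3),
    )
    p.validate()
    return p


@pytest.fixture()
def toy_params() -> SpeciesParams:
    return make_toy_params()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240214)
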