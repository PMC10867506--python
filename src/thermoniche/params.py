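"""Species physiology containers for the Wisconsin bioenergetics engine.

The engine treats every physiological constant as data: the two shipped
parameter sets (lake trout, Chinook salmon) live in YAML files under
``thermoniche/data`` and are loaded with :func:`load_species`.  Nothing in
the engine hard-codes a species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ConfigurationError, DomainError

#: Energy released per gram of oxygen respired (J / g O2), the standard
#: oxycalorific conversion used by Fish Bioenergetics 4.0.
OXYCAL_J_PER_G_O2 = 13_560.0


@dataclass(frozen=True)
class ConsumptionParams:
    """Allometric and thermal constants of maximum consumption.

    ``CEQ`` selects the temperature dependence: 1 = exponential,
    2 = Kitchell dome, 3 = Thornton–Lessem double sigmoid.
    """

    CA: float
    CB: float
    CEQ: int
    CQ: float
    CTO: float = 0.0
    CTM: float = 0.0
    CTL: float = 0.0
    CK1: float = 0.0
    CK4: float = 0.0

    def validate(self) -> None:
        if self.CEQ not in (1, 2, 3):
            raise ConfigurationError(f"CEQ must be 1, 2 or 3, got {self.CEQ}")
        if self.CA <= 0:
            raise ConfigurationError("CA must be positive")
        if self.CEQ == 2 and not self.CTO < self.CTM:
            raise ConfigurationError("CEQ=2 requires CTO < CTM")
        if self.CEQ == 3:
            if not (self.CTO < self.CTM <= self.CTL):
                raise ConfigurationError("CEQ=3 requires CTO < CTM <= CTL")
            if self.CTO <= self.CQ:
                raise ConfigurationError("CEQ=3 requires CQ < CTO")
            for k in ("CK1", "CK4"):
                v = getattr(self, k)
                if not 0.0 < v < 1.0:
                    raise ConfigurationError(f"{k} must lie in (0, 1), got {v}")


@dataclass(frozen=True)
class RespirationParams:
    """Standard metabolism, activity multiplier and SDA constants.

    ``REQ`` selects the temperature dependence: 1 = exponential with a
    swimming-speed activity term, 2 = Kitchell dome with constant activity.
    """

    RA: float
    RB: float
    REQ: int
    RQ: float
    RTO: float = 0.0
    RTM: float = 0.0
    RTL: float = 0.0
    RK1: float = 0.0
    RK4: float = 0.0
    ACT: float = 1.0
    BACT: float = 0.0
    SDA: float = 0.0

    def validate(self) -> None:
        if self.REQ not in (1, 2):
            raise ConfigurationError(f"REQ must be 1 or 2, got {self.REQ}")
        if self.RA <= 0:
            raise ConfigurationError("RA must be positive")
        if not 0.0 <= self.SDA < 1.0:
            raise ConfigurationError("SDA must lie in [0, 1)")
        if self.REQ == 2 and not self.RTO < self.RTM:
            raise ConfigurationError("REQ=2 requires RTO < RTM")


@dataclass(frozen=True)
class WasteParams:
    """Egestion (F) and excretion (U) constants; FEQ/UEQ select the form."""

    FEQ: int
    UEQ: int
    FA: float
    FB: float = 0.0
    FG: float = 0.0
    UA: float = 0.0
    UB: float = 0.0
    UG: float = 0.0

    def validate(self) -> None:
        if self.FEQ not in (1, 2, 3):
            raise ConfigurationError(f"FEQ must be 1, 2 or 3, got {self.FEQ}")
        if self.UEQ not in (1, 2, 3):
            raise ConfigurationError(f"UEQ must be 1, 2 or 3, got {self.UEQ}")


@dataclass(frozen=True)
class SpeciesParams:
    """All physiological constants plus scenario metadata for one species."""

    name: str
    consumption: ConsumptionParams
    respiration: RespirationParams
    waste: WasteParams
    oxycal: float = OXYCAL_J_PER_G_O2
    optimum_temp: float = 10.0
    sim_start: tuple[int, int] = (4, 1)  # (month, day)
    start_weight: float = 100.0
    age_span: tuple[int, int] = (1, 2)
    #: optional one-year endpoints (start g, end g) used for the
    #: age-specific consumption comparison
    age_specific_endpoints: tuple[float, float] | None = None

    def validate(self) -> None:
        self.consumption.validate()
        self.respiration.validate()
        self.waste.validate()
        if self.oxycal <= 0:
            raise ConfigurationError("oxycal must be positive")
        if self.start_weight <= 0:
            raise ConfigurationError("start_weight must be positive")
        a0, a1 = self.age_span
        if a1 <= a0:
            raise ConfigurationError("age_span must be (first, last) with last > first")
        m, d = self.sim_start
        if not (1 <= m <= 12 and 1 <= d <= 31):
            raise ConfigurationError(f"sim_start ({m}, {d}) is not a valid month/day")

    @property
    def n_years(self) -> int:
        return self.age_span[1] - self.age_span[0]


@dataclass(frozen=True)
class DietItem:
    prey: str
    proportion: float
    energy_density: float  # J / g wet weight
    indigestible_fraction: float


@dataclass(frozen=True)
class DietSchedule:
    """Prey categories with proportions summing to one.

    The engine only ever uses two aggregates of the schedule: the
    proportion-weighted mean prey energy density and the
    proportion-weighted indigestible fraction.
    """

    items: tuple[DietItem, ...]

    def __post_init__(self) -> None:
        if not self.items:
            raise DomainError("diet schedule must contain at least one prey item")
        total = sum(i.proportion for i in self.items)
        if abs(total - 1.0) > 1e-9:
            raise DomainError(f"diet proportions must sum to 1, got {total!r}")
        for i in self.items:
            if i.energy_density <= 0:
                raise DomainError(f"prey {i.prey!r} has non-positive energy density")
            if not 0.0 <= i.indigestible_fraction < 1.0:
                raise DomainError(
                    f"prey {i.prey!r} indigestible fraction must lie in [0, 1)"
                )

    @property
    def mean_energy_density(self) -> float:
        """Proportion-weighted mean prey energy density, J/g."""
        return sum(i.proportion * i.energy_density for i in self.items)

    @property
    def mean_indigestible(self) -> float:
        """Proportion-weighted indigestible fraction of the ration."""
        return sum(i.proportion * i.indigestible_fraction for i in self.items)


# ---------------------------------------------------------------------------
# YAML (de)serialisation

def _species_from_mapping(doc: Mapping) -> SpeciesParams:
    try:
        sp = SpeciesParams(
            name=str(doc["name"]),
            consumption=ConsumptionParams(**doc["consumption"]),
            respiration=RespirationParams(**doc["respiration"]),
            waste=WasteParams(**doc["waste"]),
            oxycal=float(doc.get("oxycal", OXYCAL_J_PER_G_O2)),
            optimum_temp=float(doc["optimum_temp"]),
            sim_start=tuple(doc["sim_start"]),
            start_weight=float(doc["start_weight"]),
            age_span=tuple(doc["age_span"]),
            age_specific_endpoints=(
                tuple(doc["age_specific_endpoints"])
                if doc.get("age_specific_endpoints")
                else None
            ),
        )
    except KeyError as exc:  # missing section or field
        raise ConfigurationError(f"species file missing field {exc}") from exc
    except TypeError as exc:
        raise ConfigurationError(f"species file malformed: {exc}") from exc
    sp.validate()
    return sp


def load_species(source: str | Path) -> SpeciesParams:
    """Load a species parameter file.

    ``source`` is either a path to a YAML file or the name of a packaged
    species (``"lake_trout"``, ``"chinook_salmon"``).
    """
    path = Path(source)
    if not path.suffix and not path.exists():
        ref = resources.files("thermoniche.data") / f"{source}.yaml"
        text = ref.read_text()
    else:
        text = Path(source).read_text()
    return _species_from_mapping(yaml.safe_load(text))


def packaged_species() -> tuple[str, ...]:
    """Names of the species parameter files shipped with the package."""
    return ("lake_trout", "chinook_salmon")
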