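"""Exception hierarchy for thermoniche."""


class ThermoNicheError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ThermoNicheError):
    """Invalid physiological parameters or form selectors."""


class DomainError(ThermoNicheError, ValueError):
    """An argument is outside its physical domain (negative weight, etc.)."""


class NumericalRangeError(ThermoNicheError):
    """An intermediate quantity left its admissible range (e.g. egestion
    proportion outside [0, 1])."""


class SimulationError(ThermoNicheError):
    """A daily mass-balance step failed (e.g. starvation collapse)."""


class FitError(ThermoNicheError):
    """A root-finding / regression fit could not be completed."""


class ScenarioGapError(ThermoNicheError):
    """A temperature node window contains no data."""


class SchemaError(ThermoNicheError):
    """A file does not match the expected column schema or row constraints."""
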