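"""Exception hierarchy shared across the package."""


class CmumdError(Exception):
    """Base class for all package errors."""


class ParameterError(CmumdError, ValueError):
    """An argument value is outside its valid domain."""


class GeometryError(CmumdError, ValueError):
    """Regions, boxes or membranes are geometrically inconsistent."""


class ConsistencyError(CmumdError, ValueError):
    """Controller bookkeeping (regions vs species vs concentrations) disagrees."""


class PackingError(CmumdError, ValueError):
    """Requested particle density cannot be placed without overlap."""


class InterfaceNotFoundError(CmumdError, RuntimeError):
    """The solvent profile never crosses the detection threshold."""


class NumericalBlowupError(CmumdError, RuntimeError):
    """Forces or coordinates became non-finite; carries the step index."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class SimulationStop(CmumdError, RuntimeError):
    """Controlled stop of a run (e.g. the slab in a dual-face setup is exhausted)."""


class SizingError(CmumdError, ValueError):
    """Reservoir or box too small for the requested measurement window."""


class ConfigError(CmumdError, ValueError):
    """Run-configuration file failed validation."""
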