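"""Exception hierarchy for the simulator."""


class WkloopError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(WkloopError, ValueError):
    """A muscle or ventricle geometry violates its invariants."""


class InvalidStateError(WkloopError, ValueError):
    """A dynamic state (radius, volume, pressure) left its valid domain."""


class InvalidStepError(WkloopError, ValueError):
    """An integrator was asked for a non-positive or otherwise invalid step."""


class ConfigError(WkloopError, ValueError):
    """A run configuration failed validation; message lists every violation."""


class SimulationError(WkloopError, RuntimeError):
    """The engine aborted mid-run; message names the offending step and time."""
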