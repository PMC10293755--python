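"""Exception hierarchy shared across the package."""


class ThermoSpreadError(Exception):
    """Base class for all package errors."""


class SequenceFormatError(ThermoSpreadError, ValueError):
    """A thermogram file or directory does not match the expected layout."""


class ConfigError(ThermoSpreadError, ValueError):
    """A scenario / run configuration violates a precondition."""


class StabilityError(ConfigError):
    """The explicit solver time step violates the stability bound."""


class DegenerateFiducialError(ThermoSpreadError, ValueError):
    """Fiducial endpoints coincide; no pixel scale can be derived."""
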