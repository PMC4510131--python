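"""Exception hierarchy shared across the package."""


class MicrostatError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MicrostatError):
    """A configuration value or combination of values is invalid."""


class DomainError(MicrostatError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class StateError(MicrostatError):
    """A culture state is physically inconsistent (negative density, ...)."""


class IntegrationError(MicrostatError):
    """The growth integrator produced a non-finite state."""


class FluidicsError(MicrostatError):
    """A valve/volume operation is inconsistent with the vessel."""


class OverflowGuardError(FluidicsError):
    """A requested delivery would overfill the culture vessel."""


class FitError(MicrostatError):
    """A regression cannot be computed from the given points."""


class LogFormatError(MicrostatError):
    """An experiment log file is malformed."""
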