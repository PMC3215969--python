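"""Exception types shared across the package."""


class ElectroFBAError(Exception):
    """Base class for all package errors."""


class FormatError(ElectroFBAError):
    """A model file could not be parsed in the named format."""


class ValidationError(ElectroFBAError):
    """An identifier or a structural invariant failed to validate."""


class ConfigurationError(ElectroFBAError):
    """A run configuration names something the model cannot satisfy."""


class SolverError(ElectroFBAError):
    """The LP solver reported a non-optimal status where one was required."""


class UnsupportedConfigError(ElectroFBAError):
    """A toy configuration is outside the closed-form oracle family."""
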