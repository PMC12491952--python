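"""Exception hierarchy. Categories mirror the CLI exit-code classes."""


class PopccdgError(Exception):
    """Base class for all package errors."""

    category = "internal"


class ConfigurationError(PopccdgError):
    category = "config"


class ValidationError(PopccdgError):
    category = "input"


class InputIOError(PopccdgError):
    category = "input"


class ConsistencyError(PopccdgError):
    category = "input"


class ComparabilityError(PopccdgError):
    """Sketches or indexes built with incompatible parameters."""

    category = "input"


class EstimationError(PopccdgError):
    category = "internal"


class RefinerError(PopccdgError):
    category = "refiner"
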