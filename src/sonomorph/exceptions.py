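"""Exception hierarchy shared across the package."""


class SonomorphError(Exception):
    """Base class for all package errors."""


class ConfigError(SonomorphError, ValueError):
    """Invalid configuration or parameter value."""


class DomainError(SonomorphError, ValueError):
    """Argument outside the mathematical domain of an operation."""


class DegenerateFieldError(SonomorphError, ValueError):
    """A wave field is identically zero (no mode structure)."""


class DegenerateThresholdError(SonomorphError, ValueError):
    """Automatic thresholding is undefined (e.g. constant image)."""


class ResolutionError(SonomorphError, ValueError):
    """Requested sampling step finer than the image resolution."""


class BoundsError(SonomorphError, ValueError):
    """Coordinates outside the physical extent of a grid."""


class GeneratorError(SonomorphError, ValueError):
    """A synthetic-data request is infeasible (e.g. saturated packing)."""
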