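"""Exception hierarchy shared across the package.

CLI exit-code mapping: ValidationError (and subclasses) -> 2, IOError/OSError -> 3.
"""


class FishgazeError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(FishgazeError):
    """Input violates a documented contract (schema, geometry, contiguity)."""


class FormatError(ValidationError):
    """A file does not follow the declared plain-text schema."""


class ConfigurationError(ValidationError):
    """A configuration value is missing or inconsistent (e.g. no calibration)."""


class InsufficientDataError(ValidationError):
    """Too few observations for the requested computation."""


class DegenerateInputError(ValidationError):
    """Numerically degenerate input (e.g. a <3-pixel blob, zero-SEM group)."""
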