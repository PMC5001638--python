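"""Exception types shared across the package."""


class MADetectError(Exception):
    """Base class for all package errors."""


class InvalidInputError(MADetectError):
    """Raised when an input image, mask or table violates a precondition."""


class ConfigError(MADetectError):
    """Raised when configuration values are inconsistent (e.g. r_min > r_max)."""
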