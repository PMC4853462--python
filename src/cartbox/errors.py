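"""Exception hierarchy.

All errors raised by the library derive from :class:`CartboxError` so
callers (and the CLI) can distinguish pipeline failures from bugs.
"""


class CartboxError(Exception):
    """Base class for all cartbox errors."""


class FormatError(CartboxError, ValueError):
    """A file did not conform to one of the declared dialects."""


class ValidationError(CartboxError, ValueError):
    """An in-memory object violates a structural invariant."""


class GeometryError(CartboxError, ValueError):
    """A geometric operation received degenerate or insufficient input."""


class RegistrationError(CartboxError, RuntimeError):
    """The registration chain could not proceed."""


class RotationBoundError(RegistrationError):
    """A manual adjustment rotation exceeded the configured bound."""


class AnalysisError(CartboxError, ValueError):
    """A statistical analysis received inconsistent or empty input."""


class ConfigError(CartboxError, ValueError):
    """An unknown convention, key, or option was requested."""
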