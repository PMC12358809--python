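"""Exception types shared across the package."""


class BraingapError(Exception):
    """Base class for package-specific errors."""


class ConfigurationError(BraingapError, ValueError):
    """A configuration object or file has an invalid or missing field."""


class ValidationError(BraingapError, ValueError):
    """Input data violates a documented precondition."""


class ShapeError(BraingapError, ValueError):
    """An array has an incompatible shape; the message reports both shapes."""


class UsageError(BraingapError, TypeError):
    """An operation was called on an object of the wrong kind."""
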