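"""Exception types shared across the package."""


class ErdsKitError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ErdsKitError, ValueError):
    """Invalid generator, filter, or analysis configuration."""


class DataError(ErdsKitError, ValueError):
    """Input data violates a precondition (shape, labels, degenerate values)."""
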