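"""Exception types shared across the package."""


class ScvarcalError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ScvarcalError):
    """Malformed input data (bad identifiers, negative counts, bad intervals)."""


class ConfigurationError(ScvarcalError):
    """Inconsistent or out-of-range simulation / analysis parameters."""


class NormalizationError(ScvarcalError):
    """Size-factor computation cannot proceed (e.g. no ubiquitous gene)."""


class ThresholdUndefinedError(ScvarcalError):
    """A reliability criterion was never satisfied, so the combined
    expression threshold is undefined."""
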