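"""Exception hierarchy shared across the package."""


class HomonetError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(HomonetError, ValueError):
    """A configuration object failed validation; the message names the field."""


class ParseError(HomonetError, ValueError):
    """A malformed input record; the message carries the line number."""


class DomainError(HomonetError, ValueError):
    """A statistic is mathematically undefined on the given input."""


class DegenerateAttributeError(DomainError):
    """A categorical statistic was requested with fewer than two categories."""
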