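"""Exception hierarchy shared across the toolkit.

All nephrokit errors derive from :class:`NephrokitError` so callers (and the
CLI) can distinguish validation problems (exit code 1) from usage problems
(exit code 2, handled by click).
"""


class NephrokitError(Exception):
    """Base class for all package errors."""


class FormatError(NephrokitError):
    """A file does not conform to its declared format."""


class ValidationError(NephrokitError, ValueError):
    """An input value violates a documented precondition."""


class ConfigurationError(NephrokitError):
    """A configuration value or combination is invalid."""


class GenerationError(NephrokitError):
    """A synthetic-data generator could not satisfy its constraints."""


class FitError(NephrokitError):
    """A model fit failed to converge from every starting point."""
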