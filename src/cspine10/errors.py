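"""Exception hierarchy.

All user-facing errors derive from :class:`CSpineError` so callers (and the
CLI) can catch one type.  ``DomainError`` flags invalid physical inputs,
``ConfigurationError`` flags bad configuration or missing library entries,
``NumericalError`` flags solver breakdowns and carries step context.
"""


class CSpineError(Exception):
    """Base class for all package errors."""


class DomainError(CSpineError, ValueError):
    """A physically invalid input (non-positive force, empty curve, ...)."""


class ConfigurationError(CSpineError, ValueError):
    """Invalid configuration file, unknown key, or missing library entry."""


class NumericalError(CSpineError, RuntimeError):
    """Non-finite or inconsistent solver state; message carries step context."""
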