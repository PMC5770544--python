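"""Exception hierarchy for cytostability.

Everything raised on purpose derives from :class:`CytostabilityError` so
callers (and the CLI) can distinguish user-facing problems from bugs.
"""


class CytostabilityError(Exception):
    """Base class for all errors raised by this package."""


class InputDataError(CytostabilityError):
    """A gate-abundance table or annotation file violates the input contract."""


class DimensionMismatchError(CytostabilityError):
    """Two community states (or a state and a reference) have different lengths."""


class ConfigurationError(CytostabilityError):
    """An analysis or simulator configuration is invalid or incomplete."""


class EmptyWindowError(CytostabilityError):
    """A disturbance window contains no samples."""


class MissingReferenceError(CytostabilityError):
    """No sample is available before a disturbance onset to anchor the reference."""


class UndefinedPropertyError(CytostabilityError):
    """A stability property is mathematically undefined for the given trace.

    Examples: displacement speed when the maximal deviation occurs at the
    reference sample itself, or resilience when the system never left the
    reference state (d_max = 0, in which case resistance is 1 and the
    recovery ratio has no meaning).
    """
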