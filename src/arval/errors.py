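"""Exception hierarchy shared across the package."""


class ArvalError(Exception):
    """Base class for all package errors."""


class FormatError(ArvalError):
    """A file does not conform to the declared CSV dialect."""


class ValidationError(ArvalError):
    """A domain object violates one of its invariants."""


class SyncError(ArvalError):
    """Lag estimation is impossible (e.g. zero-variance channel)."""


class AmbiguousAlignmentError(ArvalError):
    """Two frame-alignment candidates score within the ambiguity margin."""

    def __init__(self, message: str, candidates=None):
        super().__init__(message)
        self.candidates = candidates or []


class DegenerateDataError(ArvalError):
    """A statistic is undefined on the given input (constant data, n too small)."""
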