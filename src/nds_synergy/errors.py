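"""Exception types shared across the package."""


class NDSError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(NDSError, ValueError):
    """A parameter violates its documented precondition."""


class InsufficientDataError(NDSError, ValueError):
    """Too few usable data points for the requested computation."""


class IncompleteDesignError(NDSError, ValueError):
    """An effectiveness table does not cover the diagonals required.

    Carries the list of missing (subset, step) conditions so callers can
    report exactly which wells are absent.
    """

    def __init__(self, message: str, missing=None):
        super().__init__(message)
        self.missing = list(missing) if missing is not None else []


class SchemaError(NDSError, ValueError):
    """A delimited-text file does not match its expected schema."""
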