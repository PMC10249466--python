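"""Exception hierarchy shared across the package."""


class TMRError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(TMRError, ValueError):
    """Input data violates a structural invariant (shape, names, finiteness)."""


class AlignmentError(TMRError):
    """Sample identifiers cannot be reconciled across tables."""


class ParameterError(TMRError, ValueError):
    """A user-supplied parameter is outside its allowed range."""


class InsufficientDataError(TMRError):
    """Too few observations for the requested computation."""


class DegenerateDataError(TMRError):
    """Data is degenerate for the computation (constant column, all-zero row, ...)."""


class CollinearityError(TMRError):
    """A design matrix is rank deficient."""

    def __init__(self, message, columns=None):
        super().__init__(message)
        self.columns = list(columns) if columns is not None else []


class ConfigError(TMRError):
    """An invalid study or run configuration."""
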