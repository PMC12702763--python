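"""Exception hierarchy shared across the pipeline."""


class TakeoverPLSError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(TakeoverPLSError, ValueError):
    """Invalid input data or parameters."""


class DataFormatError(ValidationError):
    """A delimited-text input could not be parsed into the expected structure."""

    def __init__(self, message: str, *, row: int | None = None, column: str | None = None):
        super().__init__(message)
        self.row = row
        self.column = column


class ZeroVarianceError(ValidationError):
    """A predictor column is constant and cannot be standardized."""

    def __init__(self, message: str, *, column: str | None = None):
        super().__init__(message)
        self.column = column


class FitError(TakeoverPLSError, RuntimeError):
    """The PLS-GLR fit (or its inner logistic solver) failed."""


class EvaluationError(TakeoverPLSError, RuntimeError):
    """A leave-one-out evaluation could not be completed."""

    def __init__(self, message: str, *, fold: int | None = None):
        super().__init__(message)
        self.fold = fold
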