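"""Exception types shared across the pipeline stages."""


class GlomopipeError(Exception):
    """Base class for all package-specific errors."""


class CalibrationError(GlomopipeError, ValueError):
    """Raised for invalid micron/pixel calibration (e.g. non-positive μm/px)."""


class InvalidParameterError(GlomopipeError, ValueError):
    """Raised for out-of-domain parameters (overlap ≥ 1, bad crop, ...)."""


class InvalidInputError(GlomopipeError, ValueError):
    """Raised for inputs violating an operation's preconditions."""


class ContractViolationError(GlomopipeError, RuntimeError):
    """Raised when a pluggable detector/segmenter backend breaks its I/O contract."""


class GenerationError(GlomopipeError, RuntimeError):
    """Raised when the synthetic generator cannot satisfy a placement constraint."""


class UndefinedResultError(GlomopipeError, ValueError):
    """Raised when a statistic is undefined for the given sample (degenerate input)."""


class MulticollinearityError(GlomopipeError, ValueError):
    """Raised on rank-deficient design matrices; carries the offending columns."""

    def __init__(self, columns, message=None):
        self.columns = list(columns)
        super().__init__(message or f"linearly dependent predictors: {self.columns}")
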