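"""Exception hierarchy shared across the pipeline stages."""


class StabdimError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(StabdimError, ValueError):
    """An argument violates a documented precondition."""


class TooShortSeriesError(InvalidArgumentError):
    """A time series is shorter than the operation requires."""


class AlignmentError(StabdimError):
    """Two gridded series do not share the same pixel/time axes."""


class NonstationaryError(InvalidArgumentError):
    """|delta| >= 1: the lag-1 autoregression would not be stationary."""


class DegeneratePixelError(StabdimError):
    """A pixel has zero variance where a scale parameter is required."""


class InsufficientDataError(StabdimError):
    """Too few observations for the requested fit."""


class DegenerateNormalizationError(StabdimError):
    """All values identical: a min-max rescaling is undefined."""


class InvalidMatrixError(StabdimError):
    """A correlation matrix is asymmetric, has a non-unit diagonal, or is
    indefinite beyond numerical tolerance."""


class UnitMismatchError(StabdimError):
    """Per-unit tables being joined do not share the same unit ids."""
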