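"""Exception hierarchy for the eitroi package.

Every error raised deliberately by this package derives from
:class:`EitRoiError`, so callers can distinguish analysis failures
(degenerate ROIs, malformed files) from programming errors.
"""


class EitRoiError(Exception):
    """Base class for all eitroi errors."""


class InvalidGeometryError(EitRoiError, ValueError):
    """Grid or phantom geometry is unusable (e.g. fewer than 2 rows/cols)."""


class EmptyInputError(EitRoiError, ValueError):
    """A frame sequence with fewer than two frames was supplied."""


class FormatError(EitRoiError, ValueError):
    """A frame/mask container is malformed (wrong shape, bad values...)."""


class MissingMetadataError(FormatError):
    """Required metadata (heart rate, sample rate, group) is absent."""


class EmptyImageError(EitRoiError, ValueError):
    """An operation needing at least one valid pixel got none."""


class InvalidParametersError(EitRoiError, ValueError):
    """Parameters are out of range (e.g. cardiac passband above Nyquist)."""


class EmptyRoiError(EitRoiError, ValueError):
    """An inhomogeneity index was requested on an empty ROI."""


class InsufficientPixelsError(EitRoiError, ValueError):
    """ROI too small for the requested statistic (CV needs >= 2 pixels)."""


class DegenerateDenominatorError(EitRoiError, ArithmeticError):
    """The sum (GI) or mean (CV) of ROI values is zero; index undefined."""


class InsufficientDataError(EitRoiError, ValueError):
    """A group-level statistic was requested with too few subjects."""


class DegenerateDataError(EitRoiError, ArithmeticError):
    """A test statistic is undefined (e.g. zero pooled variance)."""
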