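"""Exception hierarchy for flyfluor."""


class FlyfluorError(Exception):
    """Base class for all flyfluor errors."""


class FormatError(FlyfluorError):
    """Input file has the wrong structure (missing columns, mixed shapes, color images)."""


class ParseError(FlyfluorError):
    """A cell or field could not be parsed as the expected type."""


class IntegrityError(FlyfluorError):
    """Data violates an invariant (duplicate keys, impossible geometry)."""


class UnsupportedFormatError(FlyfluorError):
    """A container layout that this package does not recognize."""


class EmptySampleError(FlyfluorError):
    """An ROI yielded no pixels (entirely outside the image)."""


class DegenerateSampleError(FlyfluorError):
    """A pixel sample on which the requested statistic is undefined."""


class DegenerateDenominatorError(FlyfluorError):
    """A ratio metric whose denominator averages to zero."""


class NonSeparableWarning(UserWarning):
    """Calibration scores carry no information (all values identical)."""
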