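"""Exception hierarchy.

All package-specific failures derive from :class:`TanspecError` so callers can
catch one base class; configuration problems and malformed data are kept
distinct because the CLI maps them to different exit codes.
"""


class TanspecError(Exception):
    """Base class for all tanspec errors."""


class InvalidParameterError(TanspecError, ValueError):
    """A parameter violates its documented precondition."""


class DimensionError(TanspecError, ValueError):
    """Array shapes are mutually inconsistent."""


class DataError(TanspecError, ValueError):
    """Input data is malformed (non-finite values, length mismatch, ...)."""


class ConfigError(TanspecError, ValueError):
    """A pipeline configuration references unknown methods or is inconsistent."""


class DegenerateReferenceError(TanspecError, ZeroDivisionError):
    """White and dark reference coincide at some (pixel, channel)."""


class DegenerateSpectrumError(TanspecError, ValueError):
    """A spectrum is constant where a nonzero spread is required."""


class DegenerateFitError(TanspecError, ValueError):
    """A least-squares fit collapsed (e.g. MSC slope of zero)."""


class DegenerateTargetError(TanspecError, ValueError):
    """The response variable has zero variance."""


class InvalidMaskError(TanspecError, ValueError):
    """A region-of-interest mask selects no pixels or has the wrong shape."""


class InvalidLabelsError(TanspecError, ValueError):
    """Class labels are unusable (single class, unseen labels, ...)."""
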