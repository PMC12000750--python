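"""Exception hierarchy.

Every anticipated failure mode raises a distinct, named exception so that
callers (and the CLI) can react to specific conditions instead of parsing
messages. All exceptions derive from :class:`OsteochipError`.
"""


class OsteochipError(Exception):
    """Base class for all package-specific errors."""


# --- core_io -------------------------------------------------------------

class ChannelCountMismatchError(OsteochipError):
    """Declared channel roles do not fit the channels present in the file."""


class NonNumericPixelError(OsteochipError):
    """Image file holds a pixel type that is not integer or float."""


class InvalidMeasurementError(OsteochipError, ValueError):
    """A qPCR measurement contains non-finite or non-positive Ct values."""


class ConfigError(OsteochipError, ValueError):
    """An analysis-configuration field is outside its documented range."""


# --- synthetic_data ------------------------------------------------------

class GeometryInfeasibleError(OsteochipError):
    """Cell placement failed: the requested cells do not fit the stack."""


class InvalidDesignError(OsteochipError, ValueError):
    """A factorial design is inconsistent (e.g. zero replicates)."""


# --- imagequant ----------------------------------------------------------

class ShapeMismatchError(OsteochipError, ValueError):
    """Two volumes that must share a grid have different shapes."""


class InvariantViolationError(OsteochipError, ValueError):
    """A per-cell invariant was violated (e.g. ECM voxels > total voxels)."""


class UndefinedFractionError(OsteochipError, ZeroDivisionError):
    """A fraction over zero counted objects is undefined."""


class MissingChannelError(OsteochipError, KeyError):
    """A required channel role is absent from the stack."""


# --- mechanics -----------------------------------------------------------

class ContactNotFoundError(OsteochipError):
    """No load crossing above the baseline band: the probe never contacts."""


class InsufficientRangeError(OsteochipError):
    """The re-zeroed curve does not cover the requested fit window."""


class FitFailureError(OsteochipError):
    """The fit produced a non-positive or non-finite Young's modulus."""


class UndefinedSummaryError(OsteochipError):
    """A summary over an empty group of accepted entries is undefined."""


# --- diffusion -----------------------------------------------------------

class NonIdentifiableError(OsteochipError):
    """The series carries no temporal information; D cannot be estimated."""


# --- secretome -----------------------------------------------------------

class UnimputableAnalyteError(OsteochipError):
    """An analyte is entirely missing and cannot be imputed."""

    def __init__(self, analyte: str):
        self.analyte = analyte
        super().__init__(
            f"analyte {analyte!r} has no non-missing values; cannot impute"
        )


class EmptyTableError(OsteochipError):
    """Filtering removed every analyte."""


class ZeroVarianceError(OsteochipError, ZeroDivisionError):
    """A zero-variance column cannot be z-scored or correlated."""


class UndersizedInputError(OsteochipError, ValueError):
    """Fewer than two analytes remain; decomposition is meaningless."""
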