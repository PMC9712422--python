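"""Exception hierarchy.

Validation problems subclass :class:`ValueError`, numerical problems subclass
:class:`ArithmeticError`, so callers can catch broad builtin categories.  The
CLI maps ``EITLungValidationError`` to exit code 2 and
``EITLungNumericalError`` to exit code 3.
"""


class EITLungError(Exception):
    """Base class for all package-specific errors."""


class EITLungValidationError(EITLungError, ValueError):
    """Invalid arguments, malformed files, broken invariants."""


class EITLungNumericalError(EITLungError, ArithmeticError):
    """Numerical failures (singular systems, non-convergence)."""


# --- geometry / forward model -------------------------------------------------
class InvalidGeometryError(EITLungValidationError):
    pass


class NumericalFailureError(EITLungNumericalError):
    pass


class ContractError(EITLungValidationError):
    """Dimension or consistency mismatch between pipeline artifacts."""


# --- signal processing --------------------------------------------------------
class TooShortError(EITLungValidationError):
    pass


class AlignmentError(EITLungValidationError):
    pass


class InvalidMaskError(EITLungValidationError):
    pass


class InvalidFrequencyError(EITLungValidationError):
    pass


# --- regression ---------------------------------------------------------------
class DegenerateFitError(EITLungValidationError):
    pass


class CollinearityError(EITLungValidationError):
    pass


class UnfittedModelError(EITLungError, RuntimeError):
    pass


class UndefinedMetricError(EITLungValidationError):
    pass


# --- indicators ---------------------------------------------------------------
class NoExhaleError(EITLungValidationError):
    pass


class DegenerateCurveError(EITLungValidationError):
    pass


class TruncatedCurveError(EITLungValidationError):
    pass


class SegmentationFailureError(EITLungValidationError):
    pass


# --- guided analysis ----------------------------------------------------------
class UndefinedCVError(EITLungValidationError):
    pass


class DegenerateRegressionError(EITLungValidationError):
    pass


class UndefinedNormalizationError(EITLungValidationError):
    pass


# --- io -----------------------------------------------------------------------
class FormatError(EITLungValidationError):
    pass


class DataQualityError(EITLungValidationError):
    pass


class ConfigurationError(EITLungValidationError):
    pass
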