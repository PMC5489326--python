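"""Exception hierarchy.

Every failure mode that corresponds to a physiologically meaningful
degeneracy (no filling wave, no volume recovery, flat annulus track, ...)
gets its own type so that batch pipelines can catch and report them per
subject instead of aborting.
"""


class CmrDiastError(Exception):
    """Base class for all package errors."""


class StructuralInputError(CmrDiastError):
    """Malformed input container: inconsistent shapes, bad geometry, bad CSV."""


class InsufficientSamplingError(CmrDiastError):
    """Too few frames/samples for the requested operation."""


class ParameterError(CmrDiastError, ValueError):
    """Invalid scalar argument or simulation parameter set."""


class NoFillingError(CmrDiastError):
    """No positive filling rate after end-systole; E wave undetectable."""


class DegenerateDownslopeError(CmrDiastError):
    """E-wave downslope has non-negative fitted slope; DT undefined."""


class NoRecoveryError(CmrDiastError):
    """Volume never refills to the DVR threshold after end-systole."""


class NoRelaxationError(CmrDiastError):
    """No positive annulus lengthening rate in the early-diastolic window."""


class IncompleteMeasuresError(CmrDiastError):
    """Echo record lacks a field required for ASE grading."""


class UndefinedStatisticError(CmrDiastError):
    """Statistic undefined for the given data (zero variance, etc.)."""


class DegenerateLabelsError(CmrDiastError):
    """ROC requested with a single outcome class."""


class IncompleteMatrixError(CmrDiastError):
    """Ratings matrix with missing cells passed to the ICC."""


class EnumerationLimitError(CmrDiastError):
    """Exact-test table too large to enumerate; use the Monte-Carlo option."""
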