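"""Exception hierarchy for deepdive.

All errors derive from :class:`DeepDiveError` (itself a ``ValueError``) so
callers can catch either the package root or the builtin.
"""


class DeepDiveError(ValueError):
    """Base class for all deepdive errors."""


class FormatError(DeepDiveError):
    """Malformed input file (non-uniform timestamps, missing columns...)."""


class SpecError(DeepDiveError):
    """Infeasible or invalid simulation specification."""


class InsufficientDataError(DeepDiveError):
    """Too few samples/records for the requested statistic."""


class UndefinedStatisticError(DeepDiveError):
    """The statistic is undefined for this input (e.g. CV with zero mean)."""


class CalibrationError(DeepDiveError):
    """Threshold calibration impossible (e.g. single-class labels)."""


class EmptyRecordError(DeepDiveError):
    """An operation left no data (e.g. trimming a too-short deployment)."""
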