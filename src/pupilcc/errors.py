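"""Exception hierarchy for the pipeline.

Errors raised during file validation carry enough context (file, row) to
locate the offending input; analysis-stage errors name the subject or cell
that could not be computed.
"""


class PupilError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PupilError):
    """A delimited file does not conform to the expected schema."""


class DataError(PupilError):
    """Well-formed input violating a data invariant (e.g. non-monotone time)."""


class EmptyInputError(PupilError):
    """An operation received an empty table or trace."""


class UnrecoverableTraceError(PupilError):
    """A trace with no valid samples cannot be interpolated."""


class EmptyIntervalError(PupilError):
    """A requested time interval contains no samples."""


class ExcludedEpochError(PupilError):
    """A summary measure was requested from an excluded epoch."""


class AlignmentError(PupilError):
    """Waveform grids or subject sets do not align across conditions."""


class PairingError(AlignmentError):
    """Subjects present in one condition but not the other."""


class MulticollinearityError(PupilError):
    """Candidate predictors too strongly inter-correlated for regression."""


class InsufficientDataError(PupilError):
    """Too few observations for the requested statistic."""


class UndefinedCellError(PupilError):
    """A per-subject index is undefined because a condition cell is empty."""


class DesignConstraintError(PupilError):
    """A task-design constraint cannot be satisfied."""
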