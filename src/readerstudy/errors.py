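"""Exception hierarchy for the readerstudy pipeline.

Every error raised by this package derives from :class:`ReaderStudyError`,
so callers can catch pipeline failures without masking programming errors.
"""


class ReaderStudyError(Exception):
    """Base class for all readerstudy errors."""


class FormatError(ReaderStudyError):
    """An input file is malformed (missing columns, bad flags)."""


class ValueValidationError(ReaderStudyError, ValueError):
    """A field holds a value outside its allowed domain."""


class DesignViolationError(ReaderStudyError):
    """Assessment records conflict with the reading design
    (duplicate rows, or records for studies an observer never read)."""


class EmptyInputError(ReaderStudyError):
    """An operation received no usable data."""


class InsufficientObserversError(ReaderStudyError):
    """A finding has fewer assessments than the consensus rule requires."""


class UnknownObserverError(ReaderStudyError, KeyError):
    """An observer id is absent from the reading design."""


class DegenerateTestError(ReaderStudyError):
    """A proportion test is undefined (pooled proportion of 0 or 1)."""


class ConfigError(ReaderStudyError):
    """A configuration is internally inconsistent or infeasible."""
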