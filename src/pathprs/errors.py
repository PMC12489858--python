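"""Exception hierarchy for the pathprs pipeline.

Validation errors (bad inputs, broken invariants) are distinguished from
format errors (unparseable files) so the CLI can map them to exit codes.
"""


class PathPRSError(Exception):
    """Base class for all pathprs errors."""


class FormatError(PathPRSError):
    """A file does not conform to its declared layout."""


class ValidationError(PathPRSError):
    """Inputs violate a documented precondition or invariant."""


class UndefinedStatisticError(ValidationError):
    """A statistic is undefined for the given input (e.g. all values missing)."""


class CollinearityError(ValidationError):
    """Design matrix is rank deficient; names the offending columns."""


class ScoreUndefinedError(ValidationError):
    """A requested score has no surviving variants."""


class CalibrationError(ValidationError):
    """A target prevalence is unreachable given the planted effects."""
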