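"""Exception hierarchy for the toolkit.

Schema errors (malformed input files) are distinguished from validation
errors (well-formed but invalid values) and statistical errors (degenerate
analyses) so command-line callers can map them to distinct exit codes.
"""


class PossumAuditError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(PossumAuditError, ValueError):
    """A value violates a domain constraint (e.g. a score out of bounds)."""


class SchemaError(PossumAuditError, ValueError):
    """An input file does not conform to the cohort schema."""


class StatisticalError(PossumAuditError, ValueError):
    """An analysis cannot be performed on the given data."""


class DegenerateBandError(StatisticalError):
    """A risk band has expected deaths <= 0 or >= its patient count."""


class SeparationError(StatisticalError):
    """Perfect separation detected during logistic maximum likelihood."""


class ConvergenceError(StatisticalError):
    """Newton iterations failed to converge within the iteration budget."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace
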