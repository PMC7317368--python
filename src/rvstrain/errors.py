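"""Exception hierarchy for input validation and analysis failures.

Every validation failure raises a distinct subclass naming the offending
field, so batch drivers can report per-curve problems without aborting.
"""


class StrainAnalysisError(ValueError):
    """Base class for all rvstrain validation and analysis errors."""


class MissingColumnError(StrainAnalysisError):
    """A required column or key is absent from an input file."""


class NonNumericError(StrainAnalysisError):
    """A cell that must be numeric could not be parsed as a number."""


class MonotonicityError(StrainAnalysisError):
    """Timestamps are not strictly increasing."""


class EventOrderError(StrainAnalysisError):
    """Cardiac event annotations violate their ordering constraints."""


class EventSpanError(StrainAnalysisError):
    """An event annotation falls outside the recorded curve time span."""


class CurveShapeError(StrainAnalysisError):
    """A curve is too short, non-finite, or otherwise malformed."""


class UndefinedIndexError(StrainAnalysisError):
    """The post-systolic index is undefined (division by zero peak strain)."""


class RubricError(StrainAnalysisError):
    """The scoring rubric is malformed or does not cover an input value."""


class InfeasibleSpecError(StrainAnalysisError):
    """A synthetic curve specification is internally inconsistent."""
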