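"""Named exception classes raised by sgpath.

Every user-facing failure mode has its own class so that callers (and the
command-line front end) can report a precise error category.
"""


class SgpathError(Exception):
    """Base class for all sgpath errors."""


class ValidationError(SgpathError, ValueError):
    """Base class for problem-validation failures."""


class DimensionMismatchError(ValidationError):
    """Row/column counts of y, X, Z or groups disagree."""


class NonPositiveWeightError(ValidationError):
    """A feature weight is zero or negative (weights must be > 0)."""


class NonFiniteError(ValidationError):
    """An input array contains NaN or infinity."""


class EmptyGroupError(ValidationError):
    """A group label maps to no features after relabelling."""


class DegenerateProblemError(SgpathError):
    """The penalized gradient at the unpenalized baseline is identically
    zero (y lies in the column space of X, or Z' r0 = 0), so no finite
    lambda_max exists."""


class LineSearchError(SgpathError):
    """Backtracking shrank the step below the underflow floor (1e-30)."""


class ParseError(SgpathError, ValueError):
    """An input file could not be parsed as the expected delimited table."""


class DuplicateFeatureError(ParseError):
    """A feature identifier occurs more than once in an input file."""


class UnknownFeatureError(ParseError):
    """A groups/weights file references a feature absent from Z."""


class WeightRangeError(SgpathError, ValueError):
    """A weight-builder argument is outside its valid range (e.g. a minor
    allele frequency not in (0, 0.5])."""
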