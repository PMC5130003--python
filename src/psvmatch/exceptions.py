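"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`PsvMatchError`, so callers can catch one type at the CLI boundary.
"""


class PsvMatchError(Exception):
    """Base class for all errors raised by psvmatch."""


class FormatError(PsvMatchError):
    """An input table is missing required structure (e.g. columns)."""


class ParseError(PsvMatchError):
    """A cell of an input table could not be parsed as a number."""


class InputError(PsvMatchError, ValueError):
    """Input data violates a precondition (empty group, negative time, ...)."""


class DimensionError(PsvMatchError, ValueError):
    """Vectors or matrices have incompatible shapes."""


class AlignmentError(PsvMatchError):
    """A query cohort cannot be aligned to the reference cohort."""


class NoCutoffError(PsvMatchError):
    """No admissible dichotomization cutoff exists for a variable."""


class StratificationError(PsvMatchError):
    """No admissible multi-group cutpoint set exists."""


class FitError(PsvMatchError):
    """Signature fitting failed (too few usable variables)."""


class CoverageError(PsvMatchError):
    """Too many signature variables are missing for a query patient."""


class UndefinedStatisticError(PsvMatchError, ValueError):
    """A statistic is undefined for the given input (zero events, constant
    vector, all-zero weights, degenerate fit)."""


class ConfigError(PsvMatchError, ValueError):
    """An unknown option value (measure, vector space, scheme, ...)."""


class ModelIOError(PsvMatchError):
    """A serialized model file is unreadable or has the wrong schema."""


class CrossValidationError(PsvMatchError):
    """Too many cross-validation folds failed to stratify."""
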