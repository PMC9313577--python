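"""Exception hierarchy for repsubsets.

All errors raised on invalid scientific input derive from
:class:`RepsubsetsError`, so callers can catch one base class; each also
derives from the matching builtin (``ValueError`` / ``OSError``) so the
package behaves idiomatically when used piecemeal.
"""


class RepsubsetsError(Exception):
    """Base class for all repsubsets errors."""


class ValidationError(RepsubsetsError, ValueError):
    """A record, table row, or parameter violates an invariant."""


class DialectError(RepsubsetsError, ValueError):
    """A clonotype table does not conform to the requested dialect."""


class UndefinedStatisticError(RepsubsetsError, ValueError):
    """The requested statistic is undefined for this input (e.g. N < 2)."""


class SizeError(RepsubsetsError, ValueError):
    """A subsample size exceeds the number of available unique clonotypes."""


class InsufficientDataError(RepsubsetsError, ValueError):
    """Too few observations for the requested inference (e.g. n < 3)."""


class DegenerateDataError(RepsubsetsError, ValueError):
    """Input with zero variance where a rank statistic needs spread."""


class ClassificationError(RepsubsetsError, ValueError):
    """A cell is missing a marker the classification scheme discriminates on."""


class InfeasibleSpecError(RepsubsetsError, ValueError):
    """A synthetic-data specification cannot be satisfied."""
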