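"""Exception hierarchy.

All data-dependent failures derive from :class:`PericentroError` so the CLI
can map them onto a single "data error" exit code; programming errors
(wrong types, impossible arguments) raise the builtin exceptions directly.
"""


class PericentroError(Exception):
    """Base class for all pericentro errors."""


class InvalidParameterError(PericentroError, ValueError):
    """A parameter violates its documented domain (negative rate, even window, ...)."""


class InsufficientDataError(PericentroError, ValueError):
    """Not enough observations to compute the requested statistic."""


class MalformedInputError(PericentroError, ValueError):
    """An input record or file violates its format contract."""


class MissingAnnotationError(PericentroError, KeyError):
    """A required annotation (e.g. centromere for a chromosome) is absent."""


class DegenerateTableError(PericentroError, ValueError):
    """A contingency table has a zero margin."""


class UndefinedFoldError(PericentroError, ZeroDivisionError):
    """Fold change undefined because the denominator signal is zero."""


class PipelineError(PericentroError, RuntimeError):
    """Stage orchestration failure (missing dependency output, bad config)."""
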