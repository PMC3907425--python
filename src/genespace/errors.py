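"""Exception hierarchy shared across the toolkit."""


class GenespaceError(Exception):
    """Base class for all toolkit errors."""


class ParameterError(GenespaceError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(GenespaceError, ValueError):
    """A file does not conform to the supported format (subset)."""


class ValidationError(GenespaceError, ValueError):
    """Records fail a schema-level check (duplicates, unsortable keys...)."""


class UndefinedRatioError(GenespaceError, ZeroDivisionError):
    """A ratio whose denominator is zero was requested."""


class InsufficientCoverageError(GenespaceError, RuntimeError):
    """Sequence coverage is below the minimum for a reliable estimate."""


class SubPeriodError(GenespaceError, ValueError):
    """A repeat motif is itself a repetition of a shorter unit."""


class VocabularyError(GenespaceError, KeyError):
    """A label is outside the controlled vocabulary."""
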