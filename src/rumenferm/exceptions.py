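"""Exception hierarchy shared across the pipeline."""


class RumenFermError(Exception):
    """Base class for all package errors."""


class ValidationError(RumenFermError, ValueError):
    """An input violates a documented precondition (negative amount,
    mismatched grids, malformed table ...)."""


class UndefinedResultError(RumenFermError, ZeroDivisionError):
    """A ratio was requested with a zero denominator."""


class DegenerateFitError(RumenFermError, ValueError):
    """A curve fit was requested on data that cannot identify the model
    (e.g. an all-zero gas curve)."""
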