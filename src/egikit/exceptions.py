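"""Exception hierarchy.

All package errors derive from :class:`EgikitError` so callers can catch one
type; input/contract problems additionally derive from ``ValueError``.
"""


class EgikitError(Exception):
    """Base class for all egikit errors."""


class SchemaError(EgikitError, ValueError):
    """A delimited-text input is missing a required column."""


class ParseError(EgikitError, ValueError):
    """A cell could not be parsed; carries row/column context in the message."""


class DomainError(EgikitError, ValueError):
    """An argument violates a mathematical precondition (e.g. total starch <= 0)."""


class ExtrapolationError(EgikitError, ValueError):
    """A time outside the sampled range was requested; no extrapolation is done."""


class DegenerateDesignError(EgikitError, ValueError):
    """A regression design is rank-deficient (constant x, duplicated levels)."""


class FitError(EgikitError, RuntimeError):
    """Nonlinear fitting failed from every start; message carries diagnostics."""
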