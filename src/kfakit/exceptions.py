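"""Exception hierarchy.

Everything raised on purpose by kfakit derives from :class:`KfaError`, so
callers (and the CLI) can distinguish data problems from genuine bugs.
"""


class KfaError(Exception):
    """Base class for all kfakit errors."""


class InvalidInputError(KfaError):
    """Non-finite, malformed or inconsistent user input."""


class InvalidParameterError(KfaError):
    """A parameter outside its documented domain (e.g. mixing alpha)."""


class InvalidSchemeError(KfaError):
    """An acquisition scheme that cannot support the requested operation."""


class DesignError(KfaError):
    """Under-determined or rank-deficient estimation problem."""


class DegenerateDirectionError(KfaError):
    """Apparent diffusivity vanished along a direction; K(n) undefined."""


class InsufficientDataError(KfaError):
    """Too few valid observations to form the requested statistic."""


class UndefinedCorrelationError(KfaError):
    """Pearson correlation requested for a zero-variance sequence."""
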