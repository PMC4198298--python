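"""Exception hierarchy.

Exit-code mapping used by the CLI: validation/configuration problems -> 1,
missing upstream artifacts -> 2, numerical failures -> 3.
"""


class VagsigError(Exception):
    """Base class for all package errors."""


class ValidationError(VagsigError):
    """Invalid user input (bad values, malformed tables, empty groups)."""


class ConfigurationError(ValidationError):
    """Invalid configuration object (non-positive sizes, bad rates, ...)."""


class ParseError(ValidationError):
    """Malformed input file; message names the offending row/column."""


class InsufficientDataError(VagsigError):
    """Too few observations (pairs, events, genes) for the requested fit."""


class DegenerateDataError(VagsigError):
    """Data admit no fit: zero variance, constant covariate, collinearity."""


class DegenerateDesignError(DegenerateDataError):
    """Collinear or rank-deficient design matrix; message names columns."""


class DependencyError(VagsigError):
    """A pipeline stage is missing an upstream artifact."""


class NumericalError(VagsigError):
    """A numerical procedure failed (non-convergence, excess skipped resamples)."""
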