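"""Exception hierarchy shared across the package.

Split by exit-code class: configuration problems (bad parameters, singular
stain basis), data problems (unreadable or inconsistent inputs), and
statistics that are undefined for the given input.
"""


class Ki67Error(Exception):
    """Base class for all package errors."""


class ConfigurationError(Ki67Error):
    """Invalid parameter or configuration value."""


class InvalidInputError(Ki67Error):
    """Input data violates a precondition (shape, range, emptiness)."""


class SchemaError(InvalidInputError):
    """Tabular input is missing required columns or has the wrong types."""


class MissingDataError(InvalidInputError):
    """Records contain missing predictor values; the forest does not tolerate them."""


class UndefinedStatisticError(Ki67Error):
    """A requested statistic is undefined for the given data (e.g. zero variance)."""


class GenerationError(Ki67Error):
    """Synthetic-data request is infeasible (e.g. density vs. minimum separation)."""
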