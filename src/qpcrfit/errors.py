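"""Exception hierarchy for qpcrfit.

All package errors derive from :class:`QPCRError` so callers can catch the
whole family; value-like misuse also derives from :class:`ValueError`.
"""


class QPCRError(Exception):
    """Base class for all qpcrfit errors."""


class InvalidParameterError(QPCRError, ValueError):
    """A model or configuration parameter is outside its valid domain."""


class InvalidInputError(QPCRError, ValueError):
    """An input value violates an operation's precondition."""


class InsufficientDataError(QPCRError, ValueError):
    """Too few cycles, points or dilution levels for the requested operation."""


class DegenerateInputError(QPCRError, ValueError):
    """The input is degenerate for this operation (e.g. no template)."""


class NoAmplificationError(QPCRError):
    """The curve shows no detectable growth phase."""


class FitFailureError(QPCRError):
    """A nonlinear fit could not be obtained."""


class NoCrossingError(QPCRError):
    """Background-adjusted fluorescence never reaches the Cq threshold."""


class IngestionError(QPCRError, ValueError):
    """A data file violates the curve-table contract."""


class NumericalError(QPCRError):
    """A numerical routine failed to meet its tolerance."""


class ConfigError(QPCRError, ValueError):
    """Invalid generator or pipeline configuration."""
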