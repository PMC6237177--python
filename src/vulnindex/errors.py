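"""Exception hierarchy for district-table validation and analysis steps."""


class VulnindexError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(VulnindexError):
    """An input table is missing a required column."""


class TableParseError(VulnindexError):
    """A cell could not be parsed; message names the row and column."""


class ValidationError(VulnindexError):
    """A table or record violates a structural invariant."""


class DegenerateIndicatorError(VulnindexError):
    """A raw indicator is constant across districts, so min-max
    normalization is undefined."""


class UndefinedRateError(VulnindexError):
    """A rate was requested with a zero denominator."""


class UndefinedCorrelationError(VulnindexError):
    """Pearson correlation requested for a constant series."""
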