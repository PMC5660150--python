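"""Exception hierarchy shared across the package."""


class MetaControlError(Exception):
    """Base class for all metacontrol errors."""


class SchemaError(MetaControlError):
    """CSV header or column dictionary mismatch."""


class DataValidationError(MetaControlError):
    """One or more rows violate the data-model invariants.

    The message lists every offending row with its 1-based data-row index.
    """


class ConfigurationError(MetaControlError):
    """A filter, design spec or scenario references unknown fields/levels."""


class InsufficientDataError(MetaControlError):
    """Too few rows for the requested estimator."""


class InvalidInputError(MetaControlError):
    """Numerically illegal input (zero variance, non-positive totals...)."""


class CollinearityError(MetaControlError):
    """The design matrix is rank deficient."""

    def __init__(self, message: str, aliased_terms: tuple = ()):
        super().__init__(message)
        self.aliased_terms = tuple(aliased_terms)
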