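"""Package exception hierarchy."""

__all__ = [
    "MesothreshError",
    "DataSchemaError",
    "DataValidationError",
    "SingularDesignError",
    "ContractError",
]


class MesothreshError(Exception):
    """Base class for all package-specific errors."""


class DataSchemaError(MesothreshError):
    """An input table is missing required structure (columns, rows)."""


class DataValidationError(MesothreshError, ValueError):
    """A value violates a domain invariant or cannot be parsed."""


class SingularDesignError(MesothreshError):
    """A regression design matrix is degenerate (collinear or constant)."""


class ContractError(MesothreshError):
    """An operation was called outside its stated precondition."""
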