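"""Exception hierarchy shared across the pipeline."""


class FluidprintError(Exception):
    """Base class for all package errors."""


class SpectrumFormatError(FluidprintError):
    """Raised when an on-disk spectrum cannot be parsed or validated."""


class EmptyInputError(FluidprintError):
    """Raised when an operation receives no usable data."""


class PairingError(FluidprintError):
    """Raised when serum/urine samples cannot be matched one-to-one."""


class ConsistencyError(FluidprintError):
    """Raised on duplicate ids or mismatched metadata between artifacts."""


class ConfigError(FluidprintError):
    """Raised for invalid generator or run configuration."""


class ParameterError(FluidprintError):
    """Raised when processing parameters are incompatible with the data."""


class DomainError(FluidprintError):
    """Raised when values violate a mathematical-domain precondition."""


class SchemaError(FluidprintError):
    """Raised when a matrix/model feature space does not match expectations."""


class UndefinedSimilarityError(FluidprintError):
    """Raised when a similarity score is undefined (constant vector)."""


class UndefinedMetricError(FluidprintError):
    """Raised when a classification metric is undefined (single-class truth)."""


class EstimationError(FluidprintError):
    """Raised when a statistical model cannot be estimated."""


class ContractError(FluidprintError):
    """Raised when an operation is applied outside its allowed role
    (e.g. rebalancing test data)."""


class FormulaError(FluidprintError):
    """Raised when a molecular formula cannot be parsed."""


class CompoundLookupError(FluidprintError):
    """Raised when a compound name is absent from the packaged table."""


class DependencyError(FluidprintError):
    """Raised when a pipeline stage's upstream artifact is missing."""
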