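"""Exception hierarchy used across the package."""


class GraindryError(Exception):
    """Base class for all package errors."""


class ContractError(GraindryError, ValueError):
    """An argument violates a documented precondition."""


class ConfigurationError(GraindryError, ValueError):
    """Inconsistent metadata or configuration (e.g. x0 <= xe)."""


class DomainError(GraindryError, ValueError):
    """A model was evaluated outside its mathematical domain."""


class EstimationError(GraindryError, RuntimeError):
    """An estimator could not produce a meaningful value from the data."""


class SchemaError(GraindryError, ValueError):
    """A tabular input does not match the expected column schema."""
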