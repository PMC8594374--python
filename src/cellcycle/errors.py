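"""Exception hierarchy shared across the package."""


class CellCycleError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CellCycleError, ValueError):
    """Invalid model parameters, covariance structure or run settings."""


class LineageLengthError(CellCycleError, ValueError):
    """A lineage is too short for the requested operation."""


class DataIntegrityError(CellCycleError, ValueError):
    """A physiological variable violates a hard constraint (e.g. size <= 0)."""


class UndefinedCorrelationError(CellCycleError, ValueError):
    """Pearson correlation requested for a zero-variance series."""


class RejectionSamplingError(CellCycleError, RuntimeError):
    """Positivity rejection-resampling exhausted its attempt budget.

    The message names the offending stochastic variable.
    """

    def __init__(self, variable: str, attempts: int = 100):
        self.variable = variable
        super().__init__(
            f"rejection resampling for variable {variable!r} exhausted "
            f"{attempts} attempts; reduce the noise level"
        )


class SchemaError(CellCycleError, ValueError):
    """A lineage file does not match the documented column schema."""
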