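"""Exception hierarchy shared across the package."""


class FctbnError(Exception):
    """Base class for package-specific errors."""


class SchemaError(FctbnError):
    """A record, node, parent or covariate does not match the declared model."""


class DataError(FctbnError):
    """Input data violate an invariant (non-positive duration, single-class AUC, ...)."""


class CapacityError(FctbnError):
    """A state enumeration exceeds its configured cap."""


class ConfigError(FctbnError):
    """An unknown distribution, option or configuration value."""


class ConvergenceError(FctbnError):
    """An optimizer failed to reach its stopping criterion; carries diagnostics."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace
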