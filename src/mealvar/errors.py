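"""Exception types shared across the package."""


class MealvarError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MealvarError, ValueError):
    """A configuration value is invalid (bad marginals, unknown covariate, ...)."""


class ValidationError(MealvarError, ValueError):
    """Input data violate a schema or structural precondition."""


class EstimationError(MealvarError, RuntimeError):
    """A statistical quantity is undefined or an estimator failed."""
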