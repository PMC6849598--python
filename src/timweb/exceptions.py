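"""Exception hierarchy shared across the package."""


class TimwebError(Exception):
    """Base class for all package-specific errors."""


class ModelValidationError(TimwebError, ValueError):
    """A model specification violates one or more structural invariants.

    All violations found in one validation pass are collected and reported
    together in :attr:`errors`.
    """

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("model validation failed:\n" + "\n".join(f"  - {e}" for e in self.errors))


class DomainError(TimwebError, ValueError):
    """An input value lies outside the mathematical domain of an operation."""


class UsageError(TimwebError, ValueError):
    """An operation was called in a way its contract does not permit."""


class NumericError(TimwebError, ArithmeticError):
    """A computation produced a non-finite or otherwise unusable number."""


class SingularMatrixError(NumericError):
    """A matrix required to be invertible is singular or too ill-conditioned."""


class EquilibriumError(TimwebError, RuntimeError):
    """An equilibrium required by a metric could not be obtained."""


class IntegrationError(TimwebError, RuntimeError):
    """ODE integration failed; carries the last valid state if available."""

    def __init__(self, message, last_time=None, last_state=None):
        super().__init__(message)
        self.last_time = last_time
        self.last_state = last_state


class FitError(TimwebError, RuntimeError):
    """Nonlinear fitting failed to converge from every start point."""
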