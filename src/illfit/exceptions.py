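"""Exception types shared across the package."""


class IllfitError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(IllfitError, ValueError):
    """An argument violates a documented precondition."""


class SchemaError(InvalidInputError):
    """A records table violates the input schema; carries row-numbered messages."""

    def __init__(self, violations):
        self.violations = list(violations)
        msg = "records table failed validation:\n" + "\n".join(self.violations)
        super().__init__(msg)


class InsufficientDesignError(InvalidInputError):
    """Too few distinct food-concentration levels to fit a plateau model."""


class UndefinedRError(IllfitError, ValueError):
    """The Euler-Lotka equation has no solution (l_x * m_x <= 0)."""


class NonConvergenceError(IllfitError, RuntimeError):
    """All optimizer starts failed; carries the best partial diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class InferenceFailureError(IllfitError, RuntimeError):
    """More than half of the bootstrap refits failed; intervals are unreliable."""
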