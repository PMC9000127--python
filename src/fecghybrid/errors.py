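"""Exception hierarchy shared across the package."""


class FecgError(Exception):
    """Base class for all package errors."""


class ValidationError(FecgError):
    """Input data violates a documented invariant."""


class ConfigError(FecgError):
    """Missing or inconsistent configuration value."""


class ConvergenceError(FecgError):
    """Iterative separation failed to converge."""

    def __init__(self, message: str, n_iter: int | None = None):
        super().__init__(message)
        self.n_iter = n_iter


class RoleAssignmentError(FecgError):
    """No ICA component qualifies for a required physiological role."""


class DivergenceError(FecgError):
    """Adaptive filter weights became non-finite."""

    def __init__(self, message: str, sample_index: int | None = None):
        super().__init__(message)
        self.sample_index = sample_index


class InstabilityError(FecgError):
    """Fast transversal filter exceeded its rescue budget."""

    def __init__(self, message: str, rescue_count: int | None = None):
        super().__init__(message)
        self.rescue_count = rescue_count
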