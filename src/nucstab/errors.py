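"""Exception hierarchy for nucstab."""


class NucstabError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(NucstabError):
    """Raised for malformed, incomplete, or unrecognised configuration input."""


class ConvergenceError(NucstabError):
    """Raised when a numerical solve fails to reach its tolerance.

    Carries the residual vector (if available) so the caller can diagnose
    which balance or equilibrium condition could not be satisfied.
    """

    def __init__(self, message: str, residuals=None):
        super().__init__(message)
        self.residuals = residuals
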