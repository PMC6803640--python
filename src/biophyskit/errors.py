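"""Exception hierarchy.

Hard failures (bad inputs, solver breakdown, no answer possible) raise;
soft failures of an otherwise well-posed fit (non-convergence, degenerate
data) are reported as flags on the result object instead.
"""


class BiophysKitError(Exception):
    """Base class for all package-specific errors."""


class PreconditionError(BiophysKitError, ValueError):
    """An input violates a documented precondition (e.g. negative rate)."""


class IntegrationError(BiophysKitError, RuntimeError):
    """The ODE integrator failed; ``diagnostics`` carries solver output."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class FitFailureError(BiophysKitError, RuntimeError):
    """A fit that cannot even be attempted (e.g. non-decaying correlogram)."""


class NoConsistentSeriesError(BiophysKitError, RuntimeError):
    """No consecutive charge assignment explains the peak list."""


class InvalidSequenceError(BiophysKitError, ValueError):
    """A peptide sequence contains a non-standard residue letter."""


class InsufficientDataError(BiophysKitError, ValueError):
    """Too few points to determine the requested quantity."""
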