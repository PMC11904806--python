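"""Exception hierarchy for the MR pipeline.

Errors are split by who can fix them: configuration errors (the run
config or call arguments are wrong), input errors (the data files are
malformed), usage errors (the API was called incoherently), and
numerical failures (an estimator did not converge).
"""


class ProtMRError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ProtMRError):
    """A run configuration or estimator setting is invalid."""


class InputError(ProtMRError):
    """An input table violates its contract (duplicates, zero valid rows...)."""


class UsageError(ProtMRError):
    """The API was called with incoherent arguments (e.g. mismatched ids)."""


class InsufficientDataError(ProtMRError):
    """Too few instruments for the requested estimator."""


class UndefinedRatioError(ProtMRError):
    """Wald ratio requested with a zero exposure effect."""


class ConvergenceError(ProtMRError):
    """Iterative estimator failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class PreconditionError(ProtMRError):
    """A documented precondition of an operation does not hold."""


class InsufficientOverlapError(ProtMRError):
    """Fewer shared keys than required for a cross-cohort comparison."""
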