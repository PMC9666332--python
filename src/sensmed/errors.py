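"""Exception hierarchy.

All package errors derive from :class:`SensmedError` so callers (and the CLI)
can distinguish configuration, data, and numerical failures.
"""


class SensmedError(Exception):
    """Base class for all package errors."""


class ConfigError(SensmedError):
    """Invalid run configuration."""


class SchemaError(SensmedError):
    """A required column or parameter is missing from the input."""


class InvalidMomentsError(SensmedError):
    """Moment summary is not a valid mean/SD/correlation structure."""


class InsufficientSampleError(SensmedError):
    """Too few rows for the requested operation (e.g. exact moment matching)."""


class InvalidScenarioError(SensmedError):
    """Structural simulation scenario violates its constraints."""


class InvalidParameterError(SensmedError):
    """A numeric parameter is outside its admissible range."""


class SingularDesignError(SensmedError):
    """Collinear predictors make the least-squares problem singular."""


class InsufficientChainsError(SensmedError):
    """Convergence diagnostics need at least two chains."""


class ConvergenceError(SensmedError):
    """MCMC failed to reach the PSRF threshold; carries the report."""

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report


class ScopeError(SensmedError):
    """Two models being compared do not model the same set of variables."""


class NotApplicableError(SensmedError):
    """Operation requires a model feature (e.g. an interaction path) that is absent."""


class UndefinedReliabilityError(SensmedError):
    """Reliability coefficient undefined (zero total-score variance)."""


class DegenerateDataError(SensmedError):
    """A constant column makes a correlation or z-score undefined."""
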