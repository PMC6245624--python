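"""Exception hierarchy for cohort simulation, weighting, imputation and fitting."""


class LtfImputeError(Exception):
    """Base class for all package errors."""


class ConfigError(LtfImputeError):
    """Invalid generator or imputation configuration."""


class SchemaError(LtfImputeError):
    """Input table does not carry the expected columns or flags."""


class AlignmentError(LtfImputeError):
    """Patient identifiers of two tables do not match."""


class TracingUninformativeError(LtfImputeError):
    """Tracing found nobody; the LTF death fraction cannot be estimated."""


class DegenerateStratumError(LtfImputeError):
    """A completeness stratum has estimated cases but no complete cases."""


class FitError(LtfImputeError):
    """Model fit failed (separation, non-convergence, single-class outcome)."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class PoolingError(LtfImputeError):
    """Rubin pooling called with fewer than two imputations."""


class EmptyDataError(LtfImputeError):
    """No analyzable rows remain after dropping missing values."""
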