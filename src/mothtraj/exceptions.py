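"""Exception hierarchy shared across the package."""


class MothTrajError(Exception):
    """Base class for all package-specific errors."""


class OutOfDomainError(MothTrajError):
    """A space-time query fell outside a wind field's gridded domain.

    This is a *signal*, not a failure: the trajectory integrator consumes it
    to terminate a flight with reason ``domain_exit``.
    """

    def __init__(self, message: str, axis: str | None = None):
        super().__init__(message)
        self.axis = axis


class CalmWindError(MothTrajError):
    """Downwind direction is undefined because the wind vector is (0, 0)."""


class FieldFormatError(MothTrajError, ValueError):
    """A wind-field file is missing a required variable/dimension or is malformed."""


class ValidationError(MothTrajError, ValueError):
    """Input data violated a documented invariant (axes, trap counts, config)."""


class DegenerateSampleError(MothTrajError, ValueError):
    """All paired differences are zero; the signed-rank statistic is undefined."""


class MetricUndefinedError(MothTrajError, ValueError):
    """A trajectory metric is undefined for this pair (e.g. flight ended early)."""
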