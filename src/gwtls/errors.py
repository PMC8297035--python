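"""Exception hierarchy shared across the package.

User-input problems (schema, validation) are distinguished from numerical
failures (singular systems, undefined statistics) so the command-line layer
can map them to distinct exit codes.
"""


class GwtlsError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(GwtlsError):
    """Input table or covariate layout does not match the expected schema."""


class ValidationError(GwtlsError):
    """Configuration or data values violate a documented invariant."""


class SingularSystemError(GwtlsError):
    """A (weighted) normal-equation system is rank deficient.

    Carries ``columns`` (offending column names, when identifiable) and
    ``location`` (the regression point, for local fits).
    """

    def __init__(self, message, columns=None, location=None):
        super().__init__(message)
        self.columns = columns
        self.location = location


class UndefinedMetricError(GwtlsError):
    """A statistic is undefined for the given input (e.g. zero variance)."""


class ConvergenceWarning(UserWarning):
    """An iterative solver stopped before meeting its tolerance."""
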