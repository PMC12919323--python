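"""Exception hierarchy shared across the package."""


class StandGrowthError(Exception):
    """Base class for all package errors."""


class SchemaError(StandGrowthError):
    """A required column is missing or misnamed in an input table."""


class EmptyDataError(StandGrowthError):
    """No usable records remain after filtering."""


class DomainError(StandGrowthError):
    """An input value is outside the mathematical domain of a model form."""


class SingularDesignError(StandGrowthError):
    """The regression design matrix is rank deficient."""


class UndefinedR2Error(StandGrowthError):
    """R-squared is undefined because the response has zero variance."""


class CollinearityError(StandGrowthError):
    """Exactly collinear covariates make a VIF infinite."""

    def __init__(self, names, message=None):
        self.names = list(names)
        super().__init__(message or f"exactly collinear covariates: {self.names}")


class ScreeningError(StandGrowthError):
    """Covariate screening cannot proceed (e.g. all covariates constant)."""


class SelectionError(StandGrowthError):
    """Model selection has no converged candidate to choose from."""


class ProfileError(StandGrowthError):
    """A synthetic species profile is internally infeasible."""


class ConvergenceError(StandGrowthError):
    """Training diverged (non-finite loss)."""
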