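"""Exception hierarchy for stratsem."""


class StratsemError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(StratsemError, ValueError):
    """An argument violated a documented precondition."""


class ConfigurationInfeasibleError(StratsemError):
    """A simulation configuration implies a non-PSD per-SNP covariance.

    Carries the offending trait pair in :attr:`pair` when identifiable.
    """

    def __init__(self, message, pair=None):
        super().__init__(message)
        self.pair = pair


class EmptyOutputError(StratsemError):
    """Quality control removed every record; downstream must refuse."""


class RankDeficiencyError(StratsemError):
    """The LD-score regressor is constant; slope is unidentified."""


class InsufficientOverlapError(StratsemError):
    """Too few SNPs shared between summary statistics and LD scores."""


class TraitError(StratsemError):
    """A per-trait quantity (heritability, prevalence) is unusable.

    Carries the trait label in :attr:`trait`.
    """

    def __init__(self, message, trait=None):
        super().__init__(message)
        self.trait = trait


class ConvergenceError(StratsemError):
    """Optimizer failed the gradient criterion after multi-start.

    The best iterate found is attached as :attr:`best`.
    """

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class CollinearityError(StratsemError):
    """Predictors too strongly correlated for an interpretable fit.

    Carries the offending pair in :attr:`pair`.
    """

    def __init__(self, message, pair=None):
        super().__init__(message)
        self.pair = pair


class DegenerateContrastError(StratsemError):
    """The sampling variance of a contrast is non-positive."""
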