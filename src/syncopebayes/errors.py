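"""Package-specific exceptions."""


class SyncopeBayesError(Exception):
    """Base class for all package errors."""


class AlignmentError(SyncopeBayesError):
    """Study count tables reference different predictors or levels."""


class DegenerateTableError(SyncopeBayesError):
    """A contingency table has a zero marginal and the statistic is undefined."""


class UndefinedRatioError(SyncopeBayesError):
    """A likelihood ratio has a zero denominator."""


class UndefinedPosteriorError(SyncopeBayesError):
    """Both class likelihoods are zero; the posterior is 0/0."""


class InfeasiblePlanError(SyncopeBayesError):
    """A resampling plan targets a stratum that is empty in the source cohort."""
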