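"""Exception hierarchy for the homapanel pipeline.

Every stage raises a subclass of :class:`HomapanelError`; most also derive
from :class:`ValueError` so that generic numeric code can catch them.
"""


class HomapanelError(Exception):
    """Base class for all homapanel errors."""


class InvalidInputError(HomapanelError, ValueError):
    """Input values violate a precondition (e.g. non-positive glucose)."""


class ConfigurationError(HomapanelError, ValueError):
    """A configuration object is internally inconsistent."""


class FormatError(HomapanelError, ValueError):
    """A cohort file is malformed; the message names the offending cell."""


class EmptyPanelError(HomapanelError, ValueError):
    """The missingness filter removed every metabolite."""


class DegenerateFeatureError(HomapanelError, ValueError):
    """A feature is constant and cannot be scaled; the message names it."""


class DegenerateOutcomeError(HomapanelError, ValueError):
    """Median dichotomization would leave one class empty."""


class DegenerateInputError(HomapanelError, ValueError):
    """An input is constant where variation is required."""


class ConvergenceError(HomapanelError, RuntimeError):
    """The penalized solver did not converge; carries the last iterate."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class FoldDegeneracyError(HomapanelError, ValueError):
    """A cross-validation training fold contains a single outcome class."""


class SchemaError(HomapanelError, KeyError):
    """A required column or feature is absent; the message lists the names."""


class DegenerateDesignError(HomapanelError, ValueError):
    """A regression design matrix is rank-deficient or constant."""


class NotEstimableError(HomapanelError, ValueError):
    """A quantity is outside its formula's validity range (e.g. TG >= 400)."""


class DegenerateTableError(HomapanelError, ValueError):
    """A contingency table has a zero margin."""


class InfiniteStatisticError(HomapanelError, ValueError):
    """A test statistic is infinite (zero variance with unequal means)."""
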