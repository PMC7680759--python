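"""Exception hierarchy for hatchscreen.

All errors raised by the package derive from :class:`HatchScreenError`,
which itself derives from ``ValueError`` so that generic input validation
idioms keep working.
"""


class HatchScreenError(ValueError):
    """Base class for all hatchscreen errors."""


class UndefinedRateError(HatchScreenError):
    """A hatch rate was requested for wells with zero eggs in total."""


class UndefinedFoldChangeError(HatchScreenError):
    """Fold change requested against a control group with zero hatch rate."""


class MissingConditionError(HatchScreenError):
    """A requested condition label is absent from the dataset."""


class MissingControlError(HatchScreenError):
    """A plate lacks the control condition required for the operation."""


class LayoutError(HatchScreenError):
    """A simulated plate layout does not fit the physical plate."""


class ParameterError(HatchScreenError):
    """Invalid simulation parameters."""


class InsufficientSampleError(HatchScreenError):
    """Too few replicate observations for the requested test."""


class DegenerateVarianceError(HatchScreenError):
    """A group with zero variance reached a variance-based test."""


class DegenerateExpectationError(HatchScreenError):
    """A chi-square expectation of zero (reference rate at 0 or 1)."""


class UndefinedLossError(HatchScreenError):
    """Dose-response loss undefined because a control count is zero."""


class NoToleratedDoseError(HatchScreenError):
    """No dose in a series was graded as tolerated."""


class UndefinedZPrimeError(HatchScreenError):
    """Z' undefined because the two control means coincide."""


class InsufficientReplicationError(HatchScreenError):
    """A control condition has fewer than two replicate wells."""
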