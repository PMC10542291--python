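"""Exception hierarchy for gcknipt."""


class GckNiptError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(GckNiptError, ValueError):
    """An input violates a documented precondition."""


class SaturationError(InvalidInputError):
    """All droplets positive: concentration not identifiable from counts."""


class InconsistentAssayError(GckNiptError):
    """Channel concentrations imply a fetal fraction above 1."""


class DegenerateInputError(GckNiptError):
    """Posterior cannot be formed (e.g. fetal-fraction support entirely <= 0)."""


class IncompleteRecordError(GckNiptError):
    """A sample record lacks data required by the QC rules."""


class InvalidRecordError(GckNiptError):
    """A sample record carries contradictory flags."""


class NoEligibleScanError(GckNiptError):
    """No ultrasound scan falls inside the analysis window."""


class UndefinedAUCError(GckNiptError):
    """ROC/AUC undefined because one class is absent."""


class EmptyStudyError(GckNiptError):
    """No pregnancy is eligible for the requested analysis."""


class InfeasibleParametersError(GckNiptError, ValueError):
    """A design calculation was requested with impossible parameters."""
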