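"""Exception hierarchy for the endosym package.

Every guarded failure raises a subclass of :class:`EndosymError`, so callers
can catch one base type at pipeline boundaries while tests can assert the
specific failure mode.
"""


class EndosymError(Exception):
    """Base class for all endosym errors."""


class InvalidDesignError(EndosymError, ValueError):
    """Experimental design violates its invariants (e.g. non-positive counts)."""


class ConfigurationError(EndosymError, ValueError):
    """An effect-model or run configuration parameter is out of its domain."""


class IncompletePairError(EndosymError, ValueError):
    """A qPCR sample is missing its target or reference Ct."""


class InvalidEfficiencyError(EndosymError, ValueError):
    """Amplification efficiency outside (0, 2] (as amplification factor per cycle)."""


class MissingCalibratorError(EndosymError, KeyError):
    """The calibrator condition named by the calibrator rule is absent."""


class InvalidFluorescenceError(EndosymError, ValueError):
    """Fluorescence pair violates Fm > F0 > 0."""


class EmptyGroupError(EndosymError, ZeroDivisionError):
    """Survival percentage requested for a group with zero plants."""


class UninformativeStandardsError(EndosymError, ValueError):
    """Bradford standards cannot identify a calibration line (singular fit)."""


class MissingComponentError(EndosymError, ValueError):
    """A plant-response component is missing; no silent imputation is done."""


class AlignmentError(EndosymError, ValueError):
    """E+/E− scores to be differenced do not share genotype and salinity."""


class InsufficientGradientError(EndosymError, ValueError):
    """Fewer than three distinct latitudes available for a slope fit."""


class MixedResponseError(EndosymError, ValueError):
    """Slope fits being contrasted were computed on different responses."""


class PipelineError(EndosymError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
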