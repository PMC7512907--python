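"""Exception hierarchy shared across the pipeline stages."""


class PhsentError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(PhsentError):
    """A cohort or run configuration violates its invariants."""


class PlanInfeasibleError(PhsentError):
    """A planned cardiac cycle cannot be laid out (events overlap or overrun)."""


class NoPeaksError(PhsentError):
    """R-peak detection found no usable beats (e.g., constant ECG)."""


class InvalidFrameError(PhsentError):
    """Envelope framing parameters are incompatible with the signal length."""


class InsufficientDataError(PhsentError):
    """A segment or sequence is too short for the requested computation."""


class InsufficientCyclesError(PhsentError):
    """A subject retained too few cardiac cycles to build feature sequences."""


class MissingFeatureError(PhsentError):
    """A subject lacks one of the required feature sequences."""


class UndefinedCorrelationError(PhsentError):
    """Correlation requested on a zero-variance input."""


class DegenerateBandwidthError(PhsentError):
    """Silverman bandwidth is undefined (zero spread in a training dimension)."""


class StageContractError(PhsentError):
    """A pipeline stage received inputs violating the inter-stage contract."""
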