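"""Exception hierarchy shared across the pipeline."""


class ReachGraspError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(ReachGraspError, ValueError):
    """A configuration object violates its invariants."""


class InvalidInputError(ReachGraspError, ValueError):
    """An input value is outside its documented domain."""


class InsufficientDataError(ReachGraspError, ValueError):
    """Too few frames, trials or participants for the requested computation."""


class SchemaError(ReachGraspError, KeyError):
    """A required column or feature key is missing from a table."""


class NoMovementError(ReachGraspError, ValueError):
    """No supra-threshold wrist displacement run exists in the trial."""


class NoGraspError(ReachGraspError, ValueError):
    """No finger-opening run exists in the trial."""


class DegeneratePhaseError(ReachGraspError, ValueError):
    """A phase window is too short for the requested feature."""


class DegenerateInputError(ReachGraspError, ValueError):
    """Input carries no usable variance (e.g. all-constant matrix)."""


class UndefinedRateError(ReachGraspError, ValueError):
    """Hit or false-alarm rates undefined (a stimulus class is absent)."""


class InternalConsistencyError(ReachGraspError, ValueError):
    """A derived quantity violates a structural invariant (e.g. ROC order)."""


class NoModelError(ReachGraspError, RuntimeError):
    """No candidate mixed-model structure produced a usable fit."""


class DegenerateOutcomeError(ReachGraspError, ValueError):
    """Classification outcome has a single level."""


class StratumError(ReachGraspError, ValueError):
    """A required stratum (e.g. a goal level) is empty."""


class NoDataError(ReachGraspError, ValueError):
    """No valid samples to analyse."""


class MissingReferenceError(ReachGraspError, ValueError):
    """A required AOI reference-point track is absent."""
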